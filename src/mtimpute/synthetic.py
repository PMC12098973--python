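"""Synthetic multiplex-imaging cohorts with known ground truth.

Emulates the statistical structure the imputation analysis relies on, at
desk scale: a small cohort of patients each contributing a pre-treatment and
a post-treatment biopsy; cells arranged in spatially autocorrelated niches
so neighborhood composition carries signal; cell-type archetype expression
on the lineage markers; linear protein–protein dependencies that make
targets imputable; designated high-noise proteins that are hard to impute;
and an additive treatment shift on selected functional proteins in post
biopsies.

Per-cell expression for protein p is assembled as

    archetype[type, p] + patient_effect + sum_k coeff_k * parent_k
    + weight_p * local_fraction(designated type, 30 um)
    + treatment_shift (post biopsies only) + Normal(0, noise_sd[p])

clipped to [0, 1]. Dependency targets are evaluated after their parents, on
the parents' realized (noisy) values, so a regression of target on parents
recovers the configured coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import METADATA_COLUMNS, SingleCellTable
from .panel import ProteinPanel

#: Radius (µm) over which the neighborhood-driven expression term is
#: computed during generation — matches the mid-range feature radius.
NEIGHBORHOOD_TERM_RADIUS = 30.0


@dataclass(frozen=True)
class Dependency:
    """target = sum(coeff * parent) contribution to expression."""

    target: str
    parents: tuple[str, ...]
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.parents) != len(self.coefficients):
            raise ValueError("parents and coefficients must align")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("dependency coefficients must be finite")


@dataclass(frozen=True)
class NeighborhoodDriver:
    """Adds weight * (fraction of neighbors of `cell_type` within 30 µm)."""

    target: str
    weight: float
    cell_type: int


@dataclass
class SyntheticConfig:
    panel: ProteinPanel
    n_patients: int = 4
    biopsies_per_patient: int = 2
    cells_per_biopsy: int = 2000
    domain: tuple[float, float] = (1000.0, 1000.0)
    n_cell_types: int = 5
    n_niches_per_biopsy: int = 10
    niche_sd: float = 60.0
    archetypes: np.ndarray | None = None  # (n_cell_types, n_proteins) in [0,1]
    dependencies: tuple[Dependency, ...] = ()
    neighborhood_drivers: tuple[NeighborhoodDriver, ...] = ()
    noise_sd: dict[str, float] = field(default_factory=dict)
    default_noise_sd: float = 0.05
    treatment_proteins: tuple[str, ...] = ()
    treatment_shift: float = 0.0
    patient_effect_sd: float = 0.03
    niche_mixing_alpha: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.cells_per_biopsy < 1:
            raise ValueError("need >=1 patient and >=1 cell per biopsy")
        if self.biopsies_per_patient != 2:
            raise ValueError("cohorts are pre/post pairs: biopsies_per_patient must be 2")
        if self.n_niches_per_biopsy < 1:
            raise ValueError("need >=1 niche per biopsy")
        if self.niche_sd <= 0:
            raise ValueError("niche_sd must be positive")
        if any(sd < 0 for sd in self.noise_sd.values()) or self.default_noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.archetypes is None:
            self.archetypes = _default_archetypes(
                self.n_cell_types, len(self.panel), self.seed
            )
        self.archetypes = np.asarray(self.archetypes, float)
        if self.archetypes.shape != (self.n_cell_types, len(self.panel)):
            raise ValueError(
                f"archetypes must be ({self.n_cell_types}, {len(self.panel)})"
            )
        if self.archetypes.min() < 0 or self.archetypes.max() > 1:
            raise ValueError("archetype values must lie in [0, 1]")
        names = set(self.panel.names)
        for dep in self.dependencies:
            unknown = ({dep.target} | set(dep.parents)) - names
            if unknown:
                raise ValueError(f"dependency references unknown proteins {unknown}")
        for drv in self.neighborhood_drivers:
            if drv.target not in names:
                raise ValueError(f"unknown neighborhood target {drv.target}")
            if not 0 <= drv.cell_type < self.n_cell_types:
                raise ValueError("neighborhood driver cell_type out of range")
        if set(self.treatment_proteins) - names:
            raise ValueError("treatment proteins must be panel members")

    def sd_of(self, protein: str) -> float:
        return self.noise_sd.get(protein, self.default_noise_sd)


@dataclass
class GroundTruthRecord:
    """Per-cell latent state plus the generative choices actually used."""

    cells: pd.DataFrame  # biopsy_id, cell_id, cell_type, niche_id, nbr_fraction
    dependencies: tuple[Dependency, ...]
    neighborhood_drivers: tuple[NeighborhoodDriver, ...]
    treatment_proteins: tuple[str, ...]
    treatment_shift: float
    seed: int
    clip_rate: float = 0.0

    def write_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _default_archetypes(n_types: int, n_proteins: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed + 104729)
    arc = rng.uniform(0.05, 0.25, size=(n_types, n_proteins))
    # give each type a few distinguishing high markers
    for t in range(n_types):
        hot = rng.choice(n_proteins, size=max(2, n_proteins // n_types), replace=False)
        arc[t, hot] = rng.uniform(0.55, 0.8, size=hot.size)
    return arc


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[SingleCellTable, GroundTruthRecord]:
    """Generate a cohort table plus its ground-truth sidecar.

    Deterministic given ``config.seed``; per-biopsy RNG substreams are
    spawned from a single root sequence so biopsies are independent yet
    reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    # one child per biopsy plus one for patient effects
    n_biopsies = config.n_patients * config.biopsies_per_patient
    children = root.spawn(n_biopsies + 1)
    patient_rng = np.random.default_rng(children[-1])
    P = len(config.panel)
    patient_effects = patient_rng.normal(
        0.0, config.patient_effect_sd, size=(config.n_patients, P)
    )

    dep_targets = [d.target for d in config.dependencies]
    if len(set(dep_targets)) != len(dep_targets):
        raise ValueError("each protein may be a dependency target at most once")
    name_idx = {n: i for i, n in enumerate(config.panel.names)}

    frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    n_clipped = 0
    n_values = 0
    biopsy_no = 0
    for pi in range(config.n_patients):
        patient_id = f"P{pi + 1}"
        for tp in ("pre", "post"):
            rng = np.random.default_rng(children[biopsy_no])
            biopsy_id = f"{patient_id}_{tp}"
            n = config.cells_per_biopsy
            W, H = config.domain

            centers = rng.uniform([0, 0], [W, H], size=(config.n_niches_per_biopsy, 2))
            mixing = rng.dirichlet(
                np.full(config.n_cell_types, config.niche_mixing_alpha),
                size=config.n_niches_per_biopsy,
            )
            niche_id = rng.integers(0, config.n_niches_per_biopsy, size=n)
            pos = centers[niche_id] + rng.normal(0, config.niche_sd, size=(n, 2))
            pos = np.clip(pos, [0, 0], [W, H])
            cell_type = np.array(
                [rng.choice(config.n_cell_types, p=mixing[k]) for k in niche_id]
            )

            expr = config.archetypes[cell_type].copy()  # (n, P)
            expr += patient_effects[pi]

            # local composition within the generation radius
            nbr_fraction = np.zeros(n)
            if config.neighborhood_drivers:
                tree = cKDTree(pos)
                pairs = tree.query_pairs(NEIGHBORHOOD_TERM_RADIUS, output_type="ndarray")
                counts = np.zeros(n, int)
                type_counts = np.zeros((n, config.n_cell_types), int)
                np.add.at(counts, pairs[:, 0], 1)
                np.add.at(counts, pairs[:, 1], 1)
                np.add.at(type_counts, (pairs[:, 0], cell_type[pairs[:, 1]]), 1)
                np.add.at(type_counts, (pairs[:, 1], cell_type[pairs[:, 0]]), 1)
                for drv in config.neighborhood_drivers:
                    frac = np.where(
                        counts > 0, type_counts[:, drv.cell_type] / np.maximum(counts, 1), 0.0
                    )
                    expr[:, name_idx[drv.target]] += drv.weight * frac
                    nbr_fraction = frac  # last driver's fraction, for diagnostics

            if tp == "post" and config.treatment_proteins:
                for prot in config.treatment_proteins:
                    expr[:, name_idx[prot]] += config.treatment_shift

            noise = np.column_stack(
                [rng.normal(0, config.sd_of(p), size=n) for p in config.panel.names]
            )
            expr = expr + noise

            # dependency targets: overwrite using parents' realized values
            for dep in config.dependencies:
                j = name_idx[dep.target]
                contrib = sum(
                    c * expr[:, name_idx[par]]
                    for par, c in zip(dep.parents, dep.coefficients)
                )
                base = (
                    config.archetypes[cell_type, j]
                    + patient_effects[pi, j]
                    + noise[:, j]
                )
                for drv in config.neighborhood_drivers:
                    if drv.target == dep.target:
                        base += drv.weight * nbr_fraction
                if tp == "post" and dep.target in config.treatment_proteins:
                    base += config.treatment_shift
                expr[:, j] = base + contrib

            n_clipped += int(((expr < 0) | (expr > 1)).sum())
            n_values += expr.size
            expr = np.clip(expr, 0.0, 1.0)

            df = pd.DataFrame(
                {
                    "cell_id": [f"c{i}" for i in range(n)],
                    "patient_id": patient_id,
                    "biopsy_id": biopsy_id,
                    "timepoint": tp,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                }
            )
            for j, pname in enumerate(config.panel.names):
                df[pname] = expr[:, j]
            frames.append(df)
            truth_frames.append(
                pd.DataFrame(
                    {
                        "biopsy_id": biopsy_id,
                        "cell_id": df["cell_id"],
                        "cell_type": cell_type,
                        "niche_id": niche_id,
                        "nbr_fraction": nbr_fraction,
                    }
                )
            )
            biopsy_no += 1

    table = SingleCellTable(
        pd.concat(frames, ignore_index=True), config.panel, scaled=False
    )
    truth = GroundTruthRecord(
        cells=pd.concat(truth_frames, ignore_index=True),
        dependencies=config.dependencies,
        neighborhood_drivers=config.neighborhood_drivers,
        treatment_proteins=config.treatment_proteins,
        treatment_shift=config.treatment_shift,
        seed=config.seed,
        clip_rate=n_clipped / max(n_values, 1),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Paper-like preset

#: cell types: 0 immune, 1 stromal, 2 tumor-luminal, 3 tumor-basal, 4 mesenchymal
_PRESET_ARCHETYPES = {
    #               CD45 aSMA eCad CK19 CK14 CK17  CK7  Vim Ki67 pERK   PR EGFR  p21  pRB   AR HER2
    "immune":      [0.75, 0.10, 0.10, 0.20, 0.10, 0.10, 0.10, 0.30, 0.20, 0.25, 0.20, 0.12, 0.20, 0.10, 0.10, 0.10],
    "stromal":     [0.12, 0.70, 0.10, 0.20, 0.10, 0.10, 0.10, 0.60, 0.12, 0.30, 0.20, 0.15, 0.25, 0.10, 0.10, 0.10],
    "tumor_lum":   [0.10, 0.10, 0.55, 0.55, 0.12, 0.12, 0.65, 0.10, 0.35, 0.40, 0.50, 0.25, 0.15, 0.10, 0.12, 0.30],
    "tumor_basal": [0.10, 0.12, 0.35, 0.22, 0.60, 0.65, 0.30, 0.15, 0.45, 0.50, 0.20, 0.55, 0.20, 0.10, 0.12, 0.20],
    "mesench":     [0.12, 0.40, 0.12, 0.20, 0.12, 0.12, 0.12, 0.70, 0.25, 0.35, 0.20, 0.30, 0.30, 0.10, 0.12, 0.10],
}

#: index of the tumor-luminal type in the preset archetype ordering
PRESET_LUMINAL_TYPE = 2

#: proteins deliberately given high observation noise — the hard-to-impute
#: markers of the preset (hormone-receptor and keratin markers with very
#: variable abundance)
PRESET_HIGH_NOISE = ("CK19", "PR")
PRESET_HIGH_NOISE_SD = 0.22

#: the neighborhood-driven marker: adhesion expression responds to local
#: tumor-luminal composition, so spatial features carry causal signal
PRESET_NEIGHBORHOOD_TARGET = "eCadherin"

#: functional proteins shifted in post-treatment biopsies; post biopsies are
#: taken at tumor progression, when proliferative and MAPK signalling have
#: escaped CDK4/6 blockade, so Ki67 and pERK rise (and pRB rises indirectly
#: through its Ki67/pERK dependency)
PRESET_TREATMENT_PROTEINS = ("Ki67", "pERK")
PRESET_TREATMENT_SHIFT = 0.15

PRESET_DEPENDENCIES = (
    # RB phosphorylation tracks proliferative/signalling state
    Dependency("pRB", ("Ki67", "pERK", "EGFR"), (0.5, 0.3, 0.2)),
    # androgen receptor co-varies with the hormone axis and HER2
    Dependency("AR", ("PR", "HER2"), (0.6, 0.4)),
)


def preset_paperlike(seed: int, *, cells_per_biopsy: int = 2000) -> SyntheticConfig:
    """Cohort preset mirroring the study design: 4 HR+ breast-cancer
    patients, pre/post-treatment biopsy pairs, the default 16-marker panel.

    Includes two high-noise proteins (CK19, PR), one neighborhood-driven
    protein (eCadherin), two linear dependency targets (pRB, AR), and a
    +0.15 treatment shift on Ki67 and pERK in post biopsies.
    """
    panel = ProteinPanel.default()
    arch = np.array([_PRESET_ARCHETYPES[k] for k in _PRESET_ARCHETYPES], float)
    return SyntheticConfig(
        panel=panel,
        n_patients=4,
        biopsies_per_patient=2,
        cells_per_biopsy=cells_per_biopsy,
        domain=(1000.0, 1000.0),
        n_cell_types=5,
        n_niches_per_biopsy=10,
        niche_sd=60.0,
        archetypes=arch,
        dependencies=PRESET_DEPENDENCIES,
        neighborhood_drivers=(
            NeighborhoodDriver(
                PRESET_NEIGHBORHOOD_TARGET, weight=0.35, cell_type=PRESET_LUMINAL_TYPE
            ),
        ),
        noise_sd={p: PRESET_HIGH_NOISE_SD for p in PRESET_HIGH_NOISE},
        default_noise_sd=0.05,
        treatment_proteins=PRESET_TREATMENT_PROTEINS,
        treatment_shift=PRESET_TREATMENT_SHIFT,
        patient_effect_sd=0.03,
        seed=seed,
    )


def dependency_bearing_proteins(config: SyntheticConfig) -> list[str]:
    """Targets that a predictive model should beat the null on."""
    out = [d.target for d in config.dependencies]
    out += [d.target for d in config.neighborhood_drivers if d.target not in out]
    return out
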