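"""Patient-wise cross-validation benchmarking of imputers.

Evaluation follows a leave-one-out design in which each *patient* is the
unit of validation: all biopsies of the held-out patient form the test set
and every other patient's biopsies form the training set, so no information
from a test patient can leak into scaling, spatial features, or model
fitting. A within-patient variant trains on one biopsy of every patient and
tests on the sibling biopsy.

Because a four-patient cohort yields only four leave-one-out folds,
replicates vary the model seed and draw an 80% subsample of training cells,
giving the >30 runs per condition needed for rank-based comparisons.
Model pairs are compared with two-sided Mann-Whitney U tests on
per-replicate MAE, Benjamini-Hochberg adjusted across all comparisons in
one call.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SingleCellTable
from .models import ImputerSpec, impute, train_imputer
from .panel import ProteinPanel
from .scaling import apply_scaler, fit_scaler
from .spatial import spatial_features

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVSplit:
    mode: str  # across_patient | within_patient
    split_id: str
    train_biopsies: tuple[str, ...]
    test_biopsies: tuple[str, ...]
    held_out_patient: str | None = None

    def __post_init__(self) -> None:
        if set(self.train_biopsies) & set(self.test_biopsies):
            raise ValueError("train and test biopsies overlap")


def make_splits(cohort: SingleCellTable, mode: str = "across_patient") -> list[CVSplit]:
    """Build leave-one-out splits.

    ``across_patient``: one split per patient; the held-out patient's
    biopsies are all in test. ``within_patient``: one biopsy per patient in
    train, its sibling in test; both orientations (pre-in-train and
    post-in-train) are returned.
    """
    meta = cohort.data[["patient_id", "biopsy_id", "timepoint"]].drop_duplicates()
    patients = sorted(meta["patient_id"].unique())
    if mode == "across_patient":
        if len(patients) < 2:
            raise ValueError("across-patient LOOCV needs >= 2 patients")
        splits = []
        for p in patients:
            test = tuple(sorted(meta.loc[meta["patient_id"] == p, "biopsy_id"]))
            train = tuple(sorted(meta.loc[meta["patient_id"] != p, "biopsy_id"]))
            splits.append(
                CVSplit("across_patient", f"holdout_{p}", train, test, held_out_patient=p)
            )
        return splits
    if mode == "within_patient":
        counts = meta.groupby("patient_id").size()
        if (counts != 2).any():
            raise ValueError("within-patient mode needs exactly 2 biopsies per patient")
        splits = []
        for train_tp, test_tp in (("pre", "post"), ("post", "pre")):
            train = tuple(sorted(meta.loc[meta["timepoint"] == train_tp, "biopsy_id"]))
            test = tuple(sorted(meta.loc[meta["timepoint"] == test_tp, "biopsy_id"]))
            splits.append(
                CVSplit("within_patient", f"train_{train_tp}", train, test)
            )
        return splits
    raise ValueError(f"unknown split mode {mode!r}")


def compute_metrics(truth: np.ndarray, imputed: np.ndarray) -> dict[str, float]:
    """MAE, RMSE and Pearson r between ground-truth and imputed values.

    Pearson r is recorded as NaN (undefined) when either vector is
    constant, rather than 0, and is excluded from downstream averages.
    """
    truth = np.asarray(truth, float)
    imputed = np.asarray(imputed, float)
    if truth.shape != imputed.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {imputed.shape}")
    if truth.size == 0:
        raise ValueError("empty vectors")
    err = truth - imputed
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if (
        truth.size < 2
        or (truth == truth[0]).all()
        or (imputed == imputed[0]).all()
    ):
        r = float("nan")
    else:
        r = float(stats.pearsonr(truth, imputed).statistic)
    return {"mae": mae, "rmse": rmse, "pearson_r": r}


def derive_seed(base_seed: int, *parts: object) -> int:
    """Stable sub-seed below 2**31 from a base seed and context labels."""
    h = hashlib.blake2b(
        "|".join([str(base_seed), *map(str, parts)]).encode(), digest_size=4
    )
    return int.from_bytes(h.digest(), "big") % (2**31)


def _prepare_split(
    cohort: SingleCellTable,
    split: CVSplit,
    radius: float,
    rng: np.random.Generator,
    subsample_frac: float,
    scaling_scope: str,
):
    """Scale and featurize one fold. Scaler and subsample are fit on the
    training partition only (unless ``scaling_scope='global'``)."""
    train_tbl = cohort.subset_biopsies(list(split.train_biopsies))
    test_tbl = cohort.subset_biopsies(list(split.test_biopsies))
    if subsample_frac < 1.0:
        n = train_tbl.n_cells
        keep = rng.choice(n, size=max(1, int(round(subsample_frac * n))), replace=False)
        train_tbl = train_tbl.subset_rows(np.sort(keep))
    if scaling_scope == "global":
        scaler = fit_scaler(cohort, fit_scope="global")
    else:
        scaler = fit_scaler(train_tbl, fit_scope="train_only")
    train_s = apply_scaler(train_tbl, scaler)
    test_s = apply_scaler(test_tbl, scaler)
    X_train = spatial_features(train_s, radius)
    X_test = spatial_features(test_s, radius)
    return train_tbl, test_tbl, train_s, test_s, X_train, X_test


def audit_split(
    cohort: SingleCellTable,
    split: CVSplit,
    radius: float = 0.0,
    seed: int = 0,
    *,
    subsample_frac: float = 0.8,
    scaling_scope: str = "train_only",
) -> dict[str, frozenset]:
    """Leakage audit: cell-key fingerprints of every fitting input.

    Returns the (biopsy_id, cell_id) sets used for scaler fitting, model
    training, and testing in one fold; disjointness of test keys from the
    other two is the no-leakage condition.
    """
    rng = np.random.default_rng(seed)
    train_tbl, test_tbl, train_s, _test_s, X_train, _X_test = _prepare_split(
        cohort, split, radius, rng, subsample_frac, scaling_scope
    )
    if scaling_scope == "global":
        scaler_keys = cohort.cell_keys()
    else:
        scaler_keys = fit_scaler(train_tbl).fitted_on
    return {
        "scaler_keys": scaler_keys,
        "train_keys": train_s.cell_keys(),
        "test_keys": test_tbl.cell_keys(),
    }


def run_benchmark(
    cohort: SingleCellTable,
    panel: ProteinPanel,
    specs: Sequence[ImputerSpec],
    splits: Sequence[CVSplit],
    n_replicates: int = 30,
    base_seed: int = 0,
    *,
    subsample_frac: float = 0.8,
    scaling_scope: str = "train_only",
) -> pd.DataFrame:
    """Fit/evaluate every spec on every split with replicated seeds.

    Returns one row per (spec, split, replicate, target protein) with MAE,
    RMSE, Pearson r, the derived seed, and train/test cell-count and
    fingerprint columns for leakage auditing.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    records: list[dict] = []
    for spec in specs:
        for split in splits:
            for rep in range(n_replicates):
                seed = derive_seed(
                    base_seed, spec.family, ",".join(spec.targets), spec.radius,
                    split.split_id, rep,
                )
                try:
                    records.extend(
                        _run_one(
                            cohort, panel, spec, split, rep, seed,
                            subsample_frac, scaling_scope,
                        )
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"benchmark failed for spec={spec.family}/{spec.targets} "
                        f"split={split.split_id} replicate={rep}: {exc}"
                    ) from exc
    return pd.DataFrame.from_records(records)


def _run_one(
    cohort, panel, spec, split, rep, seed, subsample_frac, scaling_scope
) -> list[dict]:
    rng = np.random.default_rng(seed)
    train_tbl, test_tbl, train_s, test_s, X_train, X_test = _prepare_split(
        cohort, split, spec.radius, rng, subsample_frac, scaling_scope
    )
    seeded = ImputerSpec(
        spec.family, spec.targets, spec.radius, dict(spec.hyperparameters), seed
    )
    trained = train_imputer(X_train, seeded, panel)
    imputed = impute(trained, X_test)
    out = []
    for target in spec.targets:
        m = compute_metrics(
            test_s.data[target].to_numpy(), imputed[target].to_numpy()
        )
        out.append(
            {
                "family": spec.family,
                "target": target,
                "radius": spec.radius,
                "split_id": split.split_id,
                "replicate": rep,
                "seed": seed,
                **m,
                "n_train": train_tbl.n_cells,
                "n_test": test_tbl.n_cells,
                "train_fingerprint": trained.train_fingerprint,
            }
        )
    logger.info(
        "benchmark %s/%s radius=%g split=%s rep=%d done",
        spec.family, ",".join(spec.targets), spec.radius, split.split_id, rep,
    )
    return out


def summarize(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per (family, target, radius): mean over per-replicate MAE scores."""
    return (
        metrics.groupby(["family", "target", "radius"], as_index=False)
        .agg(mae=("mae", "mean"), mae_sd=("mae", "std"),
             rmse=("rmse", "mean"),
             pearson_r=("pearson_r", lambda s: float(s.dropna().mean()) if s.notna().any() else float("nan")))
    )


@dataclass(frozen=True)
class StatTestResult:
    label: str
    u_statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # which group had lower median MAE


def compare_models(
    metrics: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    *,
    group_col: str = "family",
    value_col: str = "mae",
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per pair of groups, BH-adjusted together.

    ``pairs`` defaults to all pairwise combinations of the groups present.
    The BH family is all comparisons made in this one call.
    """
    groups = {g: sub[value_col].to_numpy(float) for g, sub in metrics.groupby(group_col)}
    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    results = []
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise ValueError(f"group missing from metrics: {a!r} or {b!r}")
        va, vb = groups[a], groups[b]
        if len(va) < 3 or len(vb) < 3:
            raise ValueError(f"need >= 3 records per group for {a} vs {b}")
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        direction = a if np.median(va) < np.median(vb) else b
        results.append((f"{a} vs {b}", float(res.statistic), float(res.pvalue), direction))
    raw = [r[2] for r in results]
    adjusted = multipletests(raw, method="fdr_bh")[1] if raw else []
    return pd.DataFrame(
        [
            {
                "label": lab,
                "u_statistic": u,
                "p_raw": p,
                "p_adjusted": float(min(max(adj, p), 1.0)),
                "direction": d,
            }
            for (lab, u, p, d), adj in zip(results, adjusted)
        ]
    )
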