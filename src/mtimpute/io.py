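"""Single-cell feature-table container and CSV I/O.

The canonical input is an MCMICRO-style quantification table: one row per
segmented cell with centroid coordinates (µm), per-marker mean pixel
intensity, and assorted bio-morphological columns (area, extent,
orientation, ...). Imputation uses only the marker intensities; coordinates
are retained for spatial-neighborhood features, morphology is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .panel import ProteinPanel

#: Non-protein columns every table carries, in canonical order.
METADATA_COLUMNS = ["cell_id", "patient_id", "biopsy_id", "timepoint", "x", "y"]

TIMEPOINTS = ("pre", "post")


class SchemaError(ValueError):
    """A table does not match the expected panel/metadata schema."""


@dataclass
class SingleCellTable:
    """A per-cell feature table: metadata + coordinates + panel intensities.

    ``data`` holds one row per cell with :data:`METADATA_COLUMNS` followed by
    one column per panel protein. ``scaled`` records whether intensities have
    been min-max mapped to [0, 1].
    """

    data: pd.DataFrame
    panel: ProteinPanel
    scaled: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        missing_p = [p for p in self.panel.names if p not in self.data.columns]
        if missing_p:
            raise SchemaError(f"missing panel protein columns: {missing_p}")
        self.data = self.data[METADATA_COLUMNS + self.panel.names].reset_index(
            drop=True
        )
        coords = self.data[["x", "y"]].to_numpy(float)
        if not np.isfinite(coords).all():
            raise SchemaError("non-finite cell coordinates")
        dup = self.data.duplicated(subset=["biopsy_id", "cell_id"])
        if dup.any():
            raise SchemaError(
                f"cell_id not unique within biopsy (rows {list(self.data.index[dup][:5])})"
            )
        bad_tp = set(self.data["timepoint"].unique()) - set(TIMEPOINTS)
        if bad_tp:
            raise SchemaError(f"unknown timepoints: {sorted(bad_tp)}")

    @property
    def intensities(self) -> pd.DataFrame:
        return self.data[self.panel.names]

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def biopsy_ids(self) -> list[str]:
        return sorted(self.data["biopsy_id"].unique())

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.data["patient_id"].unique())

    def subset_biopsies(self, biopsy_ids: list[str]) -> "SingleCellTable":
        mask = self.data["biopsy_id"].isin(biopsy_ids)
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def subset_rows(self, index: np.ndarray) -> "SingleCellTable":
        return replace(self, data=self.data.iloc[index].reset_index(drop=True))

    def iter_biopsies(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for bid, grp in self.data.groupby("biopsy_id", sort=True):
            yield str(bid), grp

    def cell_keys(self) -> frozenset[tuple[str, str]]:
        """(biopsy_id, cell_id) pairs — a fingerprint for leakage audits."""
        return frozenset(
            zip(self.data["biopsy_id"].astype(str), self.data["cell_id"].astype(str))
        )

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


#: Morphology columns the MCMICRO quantifier emits that imputation ignores.
_MORPHOLOGY_COLUMNS = {
    "Area",
    "MajorAxisLength",
    "MinorAxisLength",
    "Eccentricity",
    "Solidity",
    "Extent",
    "Orientation",
    "area",
    "extent",
    "orientation",
    "solidity",
    "eccentricity",
}


def load_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Load a biopsy metadata YAML: ``biopsy_id -> {patient, timepoint}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, dict[str, str]] = {}
    for bid, spec in raw.items():
        tp = str(spec["timepoint"])
        if tp not in TIMEPOINTS:
            raise ValueError(f"biopsy {bid}: timepoint must be one of {TIMEPOINTS}")
        out[str(bid)] = {"patient": str(spec["patient"]), "timepoint": tp}
    return out


def read_feature_table(
    path: str | Path,
    panel: ProteinPanel,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
    *,
    sep: str = ",",
    cell_id_col: str = "CellID",
    x_col: str = "X_centroid",
    y_col: str = "Y_centroid",
    biopsy_col: str = "biopsy_id",
    scaled: bool = False,
) -> SingleCellTable:
    """Read a quantification CSV into a :class:`SingleCellTable`.

    Parameters
    ----------
    metadata
        Map ``biopsy_id -> {"patient": ..., "timepoint": ...}``. If None the
        file itself must carry ``patient_id`` and ``timepoint`` columns.

    Only id/metadata/coordinate/protein columns are kept; morphology columns
    are dropped. A missing panel protein raises :class:`SchemaError` naming
    it; a non-numeric intensity raises ``ValueError`` with the row index.
    """
    df = pd.read_csv(path, sep=sep)

    if df.columns.str.lower().isin({"cell_id"}).any() and cell_id_col not in df:
        cell_id_col = df.columns[df.columns.str.lower() == "cell_id"][0]
    for col, label in ((cell_id_col, "cell id"), (x_col, "x"), (y_col, "y")):
        if col not in df.columns:
            raise SchemaError(f"missing {label} column {col!r}")
    missing = [p for p in panel.names if p not in df.columns]
    if missing:
        raise SchemaError(f"missing panel protein columns: {missing}")

    for p in panel.names:
        vals = pd.to_numeric(df[p], errors="coerce")
        bad = vals.isna() & df[p].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric intensity for {p} at row {int(df.index[bad][0])}"
            )
        if vals.isna().any():
            raise ValueError(
                f"missing intensity for {p} at row {int(df.index[vals.isna()][0])}"
            )
        df[p] = vals.astype(float)

    out = pd.DataFrame(
        {
            "cell_id": df[cell_id_col].astype(str),
            "x": df[x_col].astype(float),
            "y": df[y_col].astype(float),
        }
    )
    if metadata is not None:
        if biopsy_col not in df.columns:
            raise SchemaError(f"missing biopsy column {biopsy_col!r}")
        bids = df[biopsy_col].astype(str)
        unknown = set(bids.unique()) - set(metadata)
        if unknown:
            raise SchemaError(f"biopsies absent from metadata: {sorted(unknown)}")
        out["biopsy_id"] = bids
        out["patient_id"] = bids.map(lambda b: metadata[b]["patient"])
        out["timepoint"] = bids.map(lambda b: metadata[b]["timepoint"])
    else:
        for col in ("biopsy_id", "patient_id", "timepoint"):
            if col not in df.columns:
                raise SchemaError(f"missing metadata column {col!r}")
            out[col] = df[col].astype(str)
    for p in panel.names:
        out[p] = df[p]
    return SingleCellTable(out, panel, scaled=scaled)


def read_table_csv(
    path: str | Path, panel: ProteinPanel, *, scaled: bool = False
) -> SingleCellTable:
    """Read a CSV previously written by :meth:`SingleCellTable.write_csv`."""
    df = pd.read_csv(path, dtype={"cell_id": str, "patient_id": str, "biopsy_id": str})
    return SingleCellTable(df, panel, scaled=scaled)
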