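"""Per-protein min-max scaling to the [0, 1] range.

Mean pixel intensities are on arbitrary per-marker scales; all models and
error metrics operate on min-max scaled values so that an MAE of, say, 0.1
means the same thing for every protein. The scaler is fit on training data
only by default (``fit_scope="train_only"``) so test extrema never leak into
the transform; a ``"global"`` scope fitting on the full cohort is available.

Degenerate (constant) proteins scale to 0; out-of-range test values clip to
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SingleCellTable
from .panel import ProteinPanel


@dataclass(frozen=True)
class ScalingModel:
    min_fit: pd.Series
    max_fit: pd.Series
    fit_scope: str = "train_only"
    fitted_on: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (self.max_fit >= self.min_fit).all():
            raise ValueError("max_fit < min_fit for some protein")

    @property
    def degenerate(self) -> list[str]:
        """Proteins whose fitted column was constant (max == min)."""
        eq = self.max_fit == self.min_fit
        return list(self.min_fit.index[eq])

    @property
    def proteins(self) -> list[str]:
        return list(self.min_fit.index)


def fit_scaler(
    table: SingleCellTable,
    panel: ProteinPanel | None = None,
    *,
    fit_scope: str = "train_only",
) -> ScalingModel:
    """Record per-protein column extrema of ``table``."""
    panel = panel or table.panel
    if table.n_cells == 0:
        raise ValueError("cannot fit a scaler on an empty table")
    if table.scaled:
        raise ValueError("table is already scaled")
    vals = table.data[panel.names]
    return ScalingModel(
        min_fit=vals.min(axis=0),
        max_fit=vals.max(axis=0),
        fit_scope=fit_scope,
        fitted_on=table.cell_keys(),
    )


def apply_scaler(table: SingleCellTable, model: ScalingModel) -> SingleCellTable:
    """Map v -> (v - min)/(max - min), clipped to [0, 1].

    Degenerate proteins map to 0. Output table is flagged ``scaled``.
    """
    missing = [p for p in table.panel.names if p not in model.proteins]
    if missing:
        raise ValueError(f"scaler missing proteins: {missing}")
    data = table.data.copy()
    for p in table.panel.names:
        lo, hi = model.min_fit[p], model.max_fit[p]
        if hi == lo:
            data[p] = 0.0
        else:
            data[p] = np.clip((data[p] - lo) / (hi - lo), 0.0, 1.0)
    return replace(table, data=data, scaled=True)
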