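"""Two-step treatment-timepoint classification with imputed proteins.

The downstream utility check: can single cells be classified as coming from
a pre- or post-treatment biopsy, and does replacing one protein's values
with imputed values help or hurt? Because not all tissue regions carry a
treatment signal, a first-stage *tile* classifier (300 µm × 300 µm tiles,
mean protein expression per tile, the studied protein excluded) selects
tiles whose timepoint it predicts correctly; a second-stage *cell*
classifier is then trained and evaluated only on cells from the selected
tiles, under three input variants: ground truth, the protein removed, and
the protein's column replaced by (non-spatial boosted-trees) imputed
values.

Evaluation is leave-one-biopsy-out with the test patient's other biopsy
also excluded from training, so no patient contributes to both sides. The
three variants of a protein share the same split/replicate seed streams so
their accuracies are paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .benchmark import derive_seed
from .io import SingleCellTable
from .models import ImputerSpec, train_trees
from .scaling import apply_scaler, fit_scaler

VARIANTS = ("ground_truth", "removed", "imputed")
DEFAULT_TILE_SIZE = 300.0


@dataclass(frozen=True)
class TileGrid:
    """Floor-quantized tile assignment; tiles never span biopsies."""

    tile_size: float
    cells: pd.DataFrame  # biopsy_id, cell_id, tile_ix, tile_iy, tile_key

    @property
    def tile_table(self) -> pd.DataFrame:
        return self.cells.drop_duplicates("tile_key")[["tile_key", "biopsy_id"]]


def assign_tiles(table: SingleCellTable, tile_size: float = DEFAULT_TILE_SIZE) -> TileGrid:
    """Map each cell to tile (floor(x/size), floor(y/size)) in its biopsy."""
    if tile_size <= 0:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    ix = np.floor(table.data["x"].to_numpy(float) / tile_size).astype(int)
    iy = np.floor(table.data["y"].to_numpy(float) / tile_size).astype(int)
    cells = pd.DataFrame(
        {
            "biopsy_id": table.data["biopsy_id"].astype(str),
            "cell_id": table.data["cell_id"].astype(str),
            "tile_ix": ix,
            "tile_iy": iy,
        }
    )
    cells["tile_key"] = (
        cells["biopsy_id"] + ":" + ix.astype(str) + ":" + iy.astype(str)
    )
    return TileGrid(tile_size=tile_size, cells=cells)


def tile_features(
    table: SingleCellTable,
    grid: TileGrid,
    exclude: str | None = None,
    *,
    min_cells: int = 1,
) -> pd.DataFrame:
    """Per-tile mean protein expression, labelled with the biopsy timepoint.

    ``exclude`` drops the studied protein from the features. Tiles exist
    only where cells exist; tiles under ``min_cells`` are dropped.
    """
    if len(grid.cells) != table.n_cells:
        raise ValueError("tile grid was not built on this table")
    proteins = [p for p in table.panel.names if p != exclude]
    if exclude is not None and exclude not in table.panel.names:
        raise ValueError(f"exclude protein {exclude!r} not in panel")
    df = table.data[["biopsy_id", "timepoint", *proteins]].copy()
    df["tile_key"] = grid.cells["tile_key"].to_numpy()
    agg = df.groupby("tile_key", sort=True).agg(
        {**{p: "mean" for p in proteins}, "biopsy_id": "first", "timepoint": "first"}
    )
    counts = df.groupby("tile_key", sort=True).size()
    agg["n_cells"] = counts
    agg = agg[agg["n_cells"] >= min_cells]
    return agg.reset_index()


def _tile_classifier(seed: int):
    import lightgbm as lgb

    return lgb.LGBMClassifier(
        n_estimators=100, num_leaves=31, learning_rate=0.1,
        random_state=seed, n_jobs=1, deterministic=True,
        force_row_wise=True, verbosity=-1,
    )


def select_concordant_tiles(
    tiles: pd.DataFrame,
    train_biopsies: Sequence[str],
    test_biopsies: Sequence[str],
    *,
    seed: int = 0,
    feature_cols: Sequence[str] | None = None,
    oof: bool = True,
) -> tuple[set[str], set[str]]:
    """Select tiles whose timepoint the tile classifier predicts correctly.

    Training-partition tiles are judged by out-of-fold prediction (or by
    resubstitution with ``oof=False``); test-partition tiles by the
    classifier fitted on all training tiles. Returns (selected train tile
    keys, selected test tile keys).
    """
    feature_cols = list(
        feature_cols
        or [c for c in tiles.columns if c not in ("tile_key", "biopsy_id", "timepoint", "n_cells")]
    )
    tr = tiles[tiles["biopsy_id"].isin(train_biopsies)]
    te = tiles[tiles["biopsy_id"].isin(test_biopsies)]
    y_tr = (tr["timepoint"] == "post").to_numpy(int)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training tiles contain a single timepoint class")
    if min(np.bincount(y_tr)) < 2:
        raise ValueError("need >= 2 training tiles per class")
    X_tr = tr[feature_cols]
    clf = _tile_classifier(seed)
    if oof:
        n_splits = min(5, int(min(np.bincount(y_tr))))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        pred_tr = cross_val_predict(clf, X_tr, y_tr, cv=cv)
    else:
        clf.fit(X_tr, y_tr)
        pred_tr = clf.predict(X_tr)
    clf_full = _tile_classifier(seed)
    clf_full.fit(X_tr, y_tr)
    selected_train = set(tr.loc[pred_tr == y_tr, "tile_key"])
    if len(te):
        y_te = (te["timepoint"] == "post").to_numpy(int)
        pred_te = clf_full.predict(te[feature_cols])
        selected_test = set(te.loc[pred_te == y_te, "tile_key"])
    else:
        selected_test = set()
    return selected_train, selected_test


def make_biopsy_splits(cohort: SingleCellTable) -> list[dict]:
    """One split per biopsy: that biopsy is the test set, biopsies of all
    *other* patients form the training set."""
    meta = cohort.data[["patient_id", "biopsy_id"]].drop_duplicates()
    splits = []
    for _, row in meta.sort_values("biopsy_id").iterrows():
        train = sorted(meta.loc[meta["patient_id"] != row["patient_id"], "biopsy_id"])
        splits.append(
            {"split_id": f"test_{row['biopsy_id']}",
             "train_biopsies": train,
             "test_biopsies": [row["biopsy_id"]]}
        )
    return splits


def run_variant_experiment(
    cohort: SingleCellTable,
    protein: str,
    variant: str,
    splits: Sequence[dict] | None = None,
    imputer_spec: ImputerSpec | None = None,
    n_replicates: int = 1,
    base_seed: int = 0,
    *,
    tile_size: float = DEFAULT_TILE_SIZE,
    min_cells_per_tile: int = 1,
    oof_selection: bool = True,
    shuffle_labels: bool = False,
) -> pd.DataFrame:
    """Cell-classifier accuracy for one (protein, variant) pair.

    Per split and replicate: scale on the training partition, select
    concordant tiles (protein excluded from the tile classifier), restrict
    to cells of selected tiles, build the variant's cell inputs, train a
    boosted-trees cell classifier, and report test accuracy. Seeds are
    derived from (protein, split, replicate) only, never the variant, so
    variants are paired. ``shuffle_labels`` permutes the cell-level
    timepoint labels (seeded) as a chance-level control.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if protein not in cohort.panel.names:
        raise ValueError(f"protein {protein!r} not in panel")
    if variant == "imputed" and imputer_spec is None:
        imputer_spec = ImputerSpec("boosted_trees", (protein,))
    splits = splits if splits is not None else make_biopsy_splits(cohort)
    records = []
    for split in splits:
        for rep in range(n_replicates):
            seed = derive_seed(base_seed, "treatment", protein, split["split_id"], rep)
            acc, n_test = _run_variant_fold(
                cohort, protein, variant, split, seed, imputer_spec,
                tile_size, min_cells_per_tile, oof_selection, shuffle_labels,
            )
            records.append(
                {
                    "protein": protein,
                    "variant": variant,
                    "split_id": split["split_id"],
                    "replicate": rep,
                    "seed": seed,
                    "accuracy": acc,
                    "n_test_cells": n_test,
                }
            )
    return pd.DataFrame.from_records(records)


def _cell_inputs(table: SingleCellTable, protein: str, variant: str,
                 imputed: np.ndarray | None) -> pd.DataFrame:
    X = table.intensities.copy()
    if variant == "removed":
        X = X.drop(columns=[protein])
    elif variant == "imputed":
        X[protein] = imputed
    return X


def _run_variant_fold(
    cohort, protein, variant, split, seed, imputer_spec,
    tile_size, min_cells, oof, shuffle_labels,
):
    train_tbl = cohort.subset_biopsies(split["train_biopsies"])
    test_tbl = cohort.subset_biopsies(split["test_biopsies"])
    scaler = fit_scaler(train_tbl)
    train_s = apply_scaler(train_tbl, scaler)
    test_s = apply_scaler(test_tbl, scaler)

    # stage 1: concordant-tile selection (protein excluded, variant-blind)
    all_s = SingleCellTable(
        pd.concat([train_s.data, test_s.data], ignore_index=True),
        cohort.panel, scaled=True,
    )
    grid = assign_tiles(all_s, tile_size)
    tiles = tile_features(all_s, grid, exclude=protein, min_cells=min_cells)
    sel_train, sel_test = select_concordant_tiles(
        tiles, split["train_biopsies"], split["test_biopsies"], seed=seed, oof=oof
    )
    keep = grid.cells["tile_key"].isin(sel_train | sel_test).to_numpy()
    n_train = train_s.n_cells
    train_keep = keep[:n_train]
    test_keep = keep[n_train:]
    train_sel = train_s.subset_rows(np.flatnonzero(train_keep))
    test_sel = test_s.subset_rows(np.flatnonzero(test_keep))
    if test_sel.n_cells == 0 or train_sel.n_cells == 0:
        raise RuntimeError(f"no cells survived tile selection in {split['split_id']}")

    # stage 2: cell classifier on the variant's inputs
    imp_train = imp_test = None
    if variant == "imputed":
        spec = ImputerSpec(
            imputer_spec.family, imputer_spec.targets, imputer_spec.radius,
            dict(imputer_spec.hyperparameters), seed,
        )
        trained = train_trees(train_sel.intensities, protein, spec)
        imp_train = trained.predict(
            train_sel.intensities.copy()
        )[protein].to_numpy()
        imp_test = trained.predict(test_sel.intensities.copy())[protein].to_numpy()

    X_train = _cell_inputs(train_sel, protein, variant, imp_train)
    X_test = _cell_inputs(test_sel, protein, variant, imp_test)
    y_train = (train_sel.data["timepoint"] == "post").to_numpy(int)
    y_test = (test_sel.data["timepoint"] == "post").to_numpy(int)
    if shuffle_labels:
        rng = np.random.default_rng(seed)
        y_train = rng.permutation(y_train)
        y_test = rng.permutation(y_test)
    clf = _tile_classifier(seed)
    clf.fit(X_train, y_train)
    acc = float((clf.predict(X_test) == y_test).mean())
    return acc, test_sel.n_cells


def compare_variants(reports: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests on per-replicate accuracy,
    BH-adjusted; reports must share identical (split, replicate) designs."""
    from .benchmark import compare_models

    all_df = pd.concat(reports, ignore_index=True)
    designs = {
        v: frozenset(zip(sub["split_id"], sub["replicate"]))
        for v, sub in all_df.groupby("variant")
    }
    if len(set(designs.values())) != 1:
        raise ValueError("variant reports have unmatched split/replicate designs")
    return compare_models(all_df, group_col="variant", value_col="accuracy")
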