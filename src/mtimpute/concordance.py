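"""Cluster- and phenotype-level agreement between ground-truth and imputed
tables.

Low per-cell error does not by itself show that imputed values preserve
biology; this module checks whether downstream analyses — unsupervised
clustering and threshold-based phenotype gating on lineage markers — give
the same answers on imputed data as on ground truth. Agreement is measured
with the adjusted Rand index (ARI), adjusted mutual information (AMI),
silhouette scores, and a macro-averaged Jaccard index over phenotype
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn import metrics as skmetrics
from sklearn.cluster import KMeans

from .io import SingleCellTable


@dataclass(frozen=True)
class ClusterAssignment:
    labels: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.size and (lab.min() < 0 or lab.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")


def cluster_cells(table: SingleCellTable, k: int = 8, seed: int = 0) -> ClusterAssignment:
    """Centroid-based (k-means) partition of scaled intensities."""
    if k < 2:
        raise ValueError("k must be >= 2 (silhouette undefined for one cluster)")
    if k > table.n_cells:
        raise ValueError(f"k={k} exceeds number of cells ({table.n_cells})")
    if not table.scaled:
        raise ValueError("cluster on scaled intensities")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(table.intensities.to_numpy(float))
    return ClusterAssignment(labels=labels, k=k, seed=seed)


def _as_labels(a) -> np.ndarray:
    return np.asarray(a.labels if isinstance(a, ClusterAssignment) else a)


def ari(a, b) -> float:
    """Adjusted Rand index; 1 iff partitions identical up to relabeling."""
    la, lb = _as_labels(a), _as_labels(b)
    if la.shape != lb.shape:
        raise ValueError("label vectors differ in length")
    return float(skmetrics.adjusted_rand_score(la, lb))


def ami(a, b) -> float:
    """Adjusted mutual information between two labelings."""
    la, lb = _as_labels(a), _as_labels(b)
    if la.shape != lb.shape:
        raise ValueError("label vectors differ in length")
    return float(skmetrics.adjusted_mutual_info_score(la, lb))


def silhouette(
    table: SingleCellTable,
    labels,
    *,
    max_cells: int = 10_000,
    seed: int = 0,
    subsample: bool = True,
) -> float:
    """Mean silhouette over cells, Euclidean distance on scaled proteins.

    Subsampled to ``max_cells`` (seeded) by default for tractability; pass
    ``subsample=False`` for the full computation.
    """
    lab = _as_labels(labels)
    if len(lab) != table.n_cells:
        raise ValueError("labels do not match table rows")
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    X = table.intensities.to_numpy(float)
    if subsample and len(lab) > max_cells:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(lab), size=max_cells, replace=False)
        X, lab = X[keep], lab[keep]
    return float(skmetrics.silhouette_score(X, lab))


@dataclass(frozen=True)
class GatingRule:
    protein: str
    threshold: float
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("gating thresholds are on the scaled [0,1] range")


@dataclass(frozen=True)
class GatingRuleSet:
    """Ordered threshold gates on lineage markers; first match wins."""

    rules: tuple[GatingRule, ...]
    fallback: str = "other"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GatingRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = tuple(
            GatingRule(str(r["protein"]), float(r["threshold"]), str(r["label"]))
            for r in raw["rules"]
        )
        return cls(rules=rules, fallback=str(raw.get("fallback", "other")))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "rules": [
                {"protein": r.protein, "threshold": r.threshold, "label": r.label}
                for r in self.rules
            ],
            "fallback": self.fallback,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def call_phenotypes(table: SingleCellTable, rules: GatingRuleSet) -> pd.Series:
    """Assign each cell the label of the first rule whose marker exceeds its
    threshold; the fallback label otherwise."""
    if not table.scaled:
        raise ValueError("gate on scaled intensities")
    missing = [r.protein for r in rules.rules if r.protein not in table.panel.names]
    if missing:
        raise ValueError(f"gating rules reference absent proteins: {missing}")
    out = pd.Series(rules.fallback, index=range(table.n_cells), dtype=object)
    unassigned = np.ones(table.n_cells, dtype=bool)
    for rule in rules.rules:
        fire = unassigned & (table.data[rule.protein].to_numpy() > rule.threshold)
        out[fire] = rule.label
        unassigned &= ~fire
    return out


def macro_jaccard(a, b) -> float:
    """Mean over labels of |a_l ∩ b_l| / |a_l ∪ b_l| (cells as set members)."""
    la, lb = np.asarray(a), np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("label vectors differ in length")
    vocab_a, vocab_b = set(la), set(lb)
    if not vocab_a & vocab_b:
        raise ValueError("label vocabularies are disjoint")
    scores = []
    for lab in sorted(vocab_a | vocab_b, key=str):
        in_a, in_b = la == lab, lb == lab
        union = np.logical_or(in_a, in_b).sum()
        scores.append(np.logical_and(in_a, in_b).sum() / union if union else 1.0)
    return float(np.mean(scores))


def micro_jaccard(a, b) -> float:
    """Pooled Jaccard: total per-label intersection over total union."""
    la, lb = np.asarray(a), np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("label vectors differ in length")
    inter = tot = 0
    for lab in set(la) | set(lb):
        in_a, in_b = la == lab, lb == lab
        inter += np.logical_and(in_a, in_b).sum()
        tot += np.logical_or(in_a, in_b).sum()
    return float(inter / tot) if tot else 1.0


def phenotype_agreement(a, b) -> dict[str, float]:
    """ARI, AMI and macro-Jaccard between two phenotype assignments."""
    la = np.asarray(a, dtype=object)
    lb = np.asarray(b, dtype=object)
    jac = macro_jaccard(la, lb)  # also validates shapes and vocabulary
    return {
        "ari": ari(la.astype(str), lb.astype(str)),
        "ami": ami(la.astype(str), lb.astype(str)),
        "macro_jaccard": jac,
    }
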