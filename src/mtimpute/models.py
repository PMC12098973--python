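"""Imputer families and the iterative autoencoder imputation loop.

Four families predict a withheld marker's per-cell abundance from the
remaining markers (optionally plus neighbor-mean features):

* ``null`` — constant train-mean imputation, the baseline any model must beat;
* ``regularized_linear`` — elastic net with internal cross-validation;
* ``boosted_trees`` — gradient-boosted regression trees (LightGBM);
* ``autoencoder`` — an encoder–decoder network reconstructing all P panel
  proteins at once, used inside an iterative imputation loop: target columns
  are initialised with the train mean (or zero), then repeatedly replaced by
  the decoder's output over ``n_iter`` encode–decode cycles, and the final
  estimate is the per-cell mean over the last ``window`` iterations.

The null, linear, and trees imputers predict exactly one protein per model;
the autoencoder can impute a whole staining round at once. All imputed
values are clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.neural_network import MLPRegressor

from .panel import ProteinPanel

FAMILIES = ("null", "regularized_linear", "boosted_trees", "autoencoder")

#: default elastic-net mixing grid for the internal cross-validation
EN_L1_RATIOS = (0.1, 0.5, 0.9)
EN_CV_FOLDS = 5

#: default boosted-trees settings
LGBM_DEFAULTS = dict(n_estimators=100, num_leaves=31, learning_rate=0.1)

#: default autoencoder shape: input -> 16 -> latent 8 -> 16 -> P outputs
AE_HIDDEN = (16, 8, 16)
AE_LATENT = 8


@dataclass(frozen=True)
class ImputerSpec:
    family: str
    targets: tuple[str, ...]
    radius: float = 0.0
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if not self.targets:
            raise ValueError("targets must be non-empty")
        if len(self.targets) > 1 and self.family != "autoencoder":
            raise ValueError(
                f"{self.family} imputes one protein per model; "
                "multi-protein (round) targets require the autoencoder"
            )

    @property
    def target(self) -> str:
        if len(self.targets) != 1:
            raise ValueError("spec has multiple targets")
        return self.targets[0]


def _check_finite(X: pd.DataFrame) -> None:
    if not np.isfinite(X.to_numpy(float)).all():
        raise ValueError("non-finite values in model input")


def _predictor_columns(
    columns: Sequence[str], targets: Sequence[str], exclude_target_neighbors: bool
) -> list[str]:
    """Input columns for single-protein models: drop the targets' own
    columns; neighbor-mean columns of the targets are kept by default (they
    are computed from observed neighbors, not from the withheld values)."""
    drop = set(targets)
    if exclude_target_neighbors:
        drop |= {c for c in columns if any(c.startswith(f"{t}_nbr") for t in targets)}
    return [c for c in columns if c not in drop]


class TrainedImputer(Protocol):
    spec: ImputerSpec
    feature_columns: list[str]

    def predict(self, X: pd.DataFrame) -> pd.DataFrame: ...


def _check_schema(trained, X: pd.DataFrame) -> None:
    if list(X.columns) != trained.input_columns:
        raise ValueError(
            "test schema does not match training schema "
            f"(trained on {len(trained.input_columns)} columns, got {len(X.columns)}; "
            "radius mismatch?)"
        )


@dataclass
class NullImputer:
    spec: ImputerSpec
    mean_: float
    input_columns: list[str]
    train_fingerprint: int = 0

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        _check_schema(self, X)
        return pd.DataFrame(
            {self.spec.target: np.full(len(X), np.clip(self.mean_, 0.0, 1.0))}
        )


@dataclass
class SingleProteinImputer:
    """Elastic-net or boosted-trees imputer for one target protein."""

    spec: ImputerSpec
    model: object
    feature_columns: list[str]
    input_columns: list[str]
    train_fingerprint: int = 0

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        _check_schema(self, X)
        raw = self.model.predict(X[self.feature_columns])
        return pd.DataFrame({self.spec.target: np.clip(raw, 0.0, 1.0)})


@dataclass
class AutoencoderImputer:
    """Encoder–decoder reconstructing every panel protein from the full
    (optionally spatially augmented) input row."""

    spec: ImputerSpec
    model: MLPRegressor
    panel: ProteinPanel
    input_columns: list[str]
    train_means: pd.Series
    train_fingerprint: int = 0

    @property
    def latent_dim(self) -> int:
        return min(self.model.hidden_layer_sizes)

    def reconstruct(self, X: pd.DataFrame) -> pd.DataFrame:
        """One encode–decode pass; returns all P proteins, clipped."""
        _check_schema(self, X)
        out = self.model.predict(X[self.input_columns].to_numpy(float))
        return pd.DataFrame(np.clip(out, 0.0, 1.0), columns=self.panel.names)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        final, _ = iterative_impute(self, X, self.spec.targets)
        return final


def _fingerprint(X: pd.DataFrame) -> int:
    return int(
        pd.util.hash_pandas_object(X.reset_index(drop=True), index=False).sum()
        % (2**63)
    )


def train_null(train: pd.DataFrame, target: str) -> NullImputer:
    """Store the train-mean of ``target``; imputes that constant."""
    if len(train) == 0:
        raise ValueError("empty training data")
    if target not in train.columns:
        raise ValueError(f"target {target!r} not in training columns")
    spec = ImputerSpec("null", (target,))
    return NullImputer(
        spec=spec,
        mean_=float(train[target].mean()),
        input_columns=list(train.columns),
        train_fingerprint=_fingerprint(train),
    )


def train_linear(
    train: pd.DataFrame, target: str, spec: ImputerSpec | None = None
) -> SingleProteinImputer:
    """Elastic net with internal k-fold CV over penalty strength and mixing."""
    spec = spec or ImputerSpec("regularized_linear", (target,))
    hp = dict(spec.hyperparameters)
    cv = int(hp.pop("cv", EN_CV_FOLDS))
    if len(train) < cv:
        raise ValueError(f"need at least {cv} rows for {cv}-fold CV, got {len(train)}")
    _check_finite(train)
    cols = _predictor_columns(
        train.columns, spec.targets, bool(hp.pop("exclude_target_neighbors", False))
    )
    model = ElasticNetCV(
        l1_ratio=list(hp.pop("l1_ratio", EN_L1_RATIOS)),
        cv=cv,
        alphas=int(hp.pop("n_alphas", 50)),
        random_state=spec.seed,
        max_iter=int(hp.pop("max_iter", 2000)),
    )
    model.fit(train[cols], train[target].to_numpy(float))
    return SingleProteinImputer(
        spec=spec,
        model=model,
        feature_columns=cols,
        input_columns=list(train.columns),
        train_fingerprint=_fingerprint(train),
    )


def train_trees(
    train: pd.DataFrame, target: str, spec: ImputerSpec | None = None
) -> SingleProteinImputer:
    """Gradient-boosted regression trees; deterministic given seed."""
    import lightgbm as lgb

    spec = spec or ImputerSpec("boosted_trees", (target,))
    if len(train) == 0:
        raise ValueError("empty training data")
    _check_finite(train)
    hp = dict(spec.hyperparameters)
    exclude = bool(hp.pop("exclude_target_neighbors", False))
    cols = _predictor_columns(train.columns, spec.targets, exclude)
    params = {**LGBM_DEFAULTS, **hp}
    model = lgb.LGBMRegressor(
        random_state=spec.seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbosity=-1,
        **params,
    )
    model.fit(train[cols], train[target].to_numpy(float))
    return SingleProteinImputer(
        spec=spec,
        model=model,
        feature_columns=cols,
        input_columns=list(train.columns),
        train_fingerprint=_fingerprint(train),
    )


def train_autoencoder(
    train: pd.DataFrame,
    panel: ProteinPanel,
    spec: ImputerSpec | None = None,
) -> AutoencoderImputer:
    """Fit the encoder–decoder to reconstruct all P proteins.

    Architecture: input (P or 2P) → 16 → latent 8 → 16 → P, ReLU hidden
    units, trained with Adam and early stopping on a held-out 10% of the
    training cells; deterministic given the spec seed.
    """
    spec = spec or ImputerSpec("autoencoder", tuple(panel.names))
    if len(train) == 0:
        raise ValueError("empty training data")
    _check_finite(train)
    hp = dict(spec.hyperparameters)
    hidden = tuple(hp.pop("hidden_layer_sizes", AE_HIDDEN))
    if min(hidden) >= len(panel):
        raise ValueError(
            f"latent dimension {min(hidden)} must be below panel size {len(panel)}"
        )
    model = MLPRegressor(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        random_state=spec.seed,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=int(hp.pop("n_iter_no_change", 10)),
        max_iter=int(hp.pop("max_iter", 300)),
        **hp,
    )
    X = train.to_numpy(float)
    Y = train[panel.names].to_numpy(float)
    # max_iter caps training cost; hitting the cap is acceptable here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, Y)
    return AutoencoderImputer(
        spec=spec,
        model=model,
        panel=panel,
        input_columns=list(train.columns),
        train_means=train[panel.names].mean(),
        train_fingerprint=_fingerprint(train),
    )


@dataclass
class ImputationTrajectory:
    """Per-iteration imputed target values from the autoencoder loop."""

    iterations: list[pd.DataFrame]
    init_mode: str
    window: int

    def __post_init__(self) -> None:
        if self.window > len(self.iterations):
            raise ValueError("window exceeds number of iterations")

    @property
    def n_iter(self) -> int:
        return len(self.iterations)

    @property
    def final(self) -> pd.DataFrame:
        """Per-cell mean over the last ``window`` iterations."""
        tail = self.iterations[-self.window :]
        return sum(df for df in tail) / len(tail)


def iterative_impute(
    ae,
    test: pd.DataFrame,
    targets: Sequence[str],
    *,
    init: str = "mean",
    n_iter: int = 10,
    window: int = 5,
) -> tuple[pd.DataFrame, ImputationTrajectory]:
    """Iteratively impute ``targets`` with a trained reconstructor.

    Target columns of ``test`` are first replaced by the training-set mean
    (``init="mean"``) or zero; each cycle runs one encode–decode pass and
    writes the decoded target values back, leaving all other columns
    untouched. The final estimate averages the last ``window`` iterations.
    """
    if init not in ("mean", "zero"):
        raise ValueError("init must be 'mean' or 'zero'")
    if window > n_iter:
        raise ValueError(f"window ({window}) must not exceed n_iter ({n_iter})")
    targets = list(targets)
    unknown = [t for t in targets if t not in ae.panel.names]
    if unknown:
        raise ValueError(f"targets not in panel: {unknown}")

    X = test.copy()
    for t in targets:
        X[t] = float(ae.train_means[t]) if init == "mean" else 0.0

    snapshots: list[pd.DataFrame] = []
    for _ in range(n_iter):
        decoded = ae.reconstruct(X)
        for t in targets:
            X[t] = decoded[t].to_numpy()
        snapshots.append(X[targets].copy().reset_index(drop=True))
    traj = ImputationTrajectory(iterations=snapshots, init_mode=init, window=window)
    return traj.final, traj


def train_imputer(train: pd.DataFrame, spec: ImputerSpec, panel: ProteinPanel):
    """Dispatch on the spec's family."""
    if spec.family == "null":
        return train_null(train, spec.target)
    if spec.family == "regularized_linear":
        return train_linear(train, spec.target, spec)
    if spec.family == "boosted_trees":
        return train_trees(train, spec.target, spec)
    return train_autoencoder(train, panel, spec)


def impute(trained, test: pd.DataFrame) -> pd.DataFrame:
    """One imputed value per cell per target protein, clipped to [0, 1]."""
    return trained.predict(test)


BUNDLE_VERSION = 1


def save_imputer(trained, directory) -> None:
    """Persist a trained imputer as a versioned bundle (spec YAML + state)."""
    import joblib
    import yaml
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spec = trained.spec
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "family": spec.family,
        "targets": list(spec.targets),
        "radius": float(spec.radius),
        "seed": int(spec.seed),
        "hyperparameters": dict(spec.hyperparameters),
    }
    with open(d / "spec.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    joblib.dump(trained, d / "model.joblib")


def load_imputer(directory):
    import joblib
    import yaml
    from pathlib import Path

    d = Path(directory)
    with open(d / "spec.yaml") as fh:
        meta = yaml.safe_load(fh)
    if meta.get("bundle_version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {meta.get('bundle_version')}")
    trained = joblib.load(d / "model.joblib")
    if trained.spec.family != meta["family"]:
        raise ValueError("bundle spec does not match serialized model")
    return trained
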