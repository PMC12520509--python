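"""Two-layer stacked ensemble decoder for spike patterns.

The model is y = g(f_r^m(X)): a bank of first-layer base learners —
L1-regularized logistic regressions, one per temporal resolution
M/(m+1), each fit on B-spline features of the spike pattern X and
bagged over R bootstrap replicas — whose per-resolution predicted
probabilities are fused by a second-layer L1-logistic meta-learner g
into one binary category prediction. L1 penalties keep the coefficient
vectors sparse (most (neuron, basis) weights exactly zero), which is
what later makes the fitted model interpretable.

Fitting is wrapped in nested cross-validation: outer folds hold out
test trials that never influence any parameter or hyperparameter;
inner folds select each learner's L1 strength by cross-entropy and
supply the out-of-fold base predictions on which the meta-learner is
trained (stacking without leakage). One independent binary model is
fit per category (one-vs-rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from . import metrics as _metrics
from .features import DEFAULT_SEGMENTS, Basis, bin_patterns, build_basis, feature_matrix

__all__ = [
    "DecoderConfig",
    "BaseLearner",
    "MetaLearner",
    "DecodingModel",
    "CategoryResult",
    "FoldModel",
    "DecodingResult",
    "fit_base_learner",
    "fit_bagged_bank",
    "fit_meta_learner",
    "nested_cv_fit_predict",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class DecoderConfig:
    """Settings for the stacked decoder.

    ``segments`` lists m + 1 per base learner (resolution = window / (m+1));
    ``l1_grid`` are inverse penalty strengths C = 1/lambda searched by the
    inner folds.
    """

    segments: tuple = DEFAULT_SEGMENTS
    order: int = 3
    grid_ms: float = 2.0
    n_replicas: int = 20
    outer_folds: int = 5
    inner_folds: int = 4
    l1_grid: tuple = (0.01, 0.0316, 0.1, 0.316, 1.0, 3.16, 10.0)
    meta_l1_grid: tuple = (0.1, 1.0, 10.0)
    stack: bool = True
    bootstrap: bool = True
    threshold: float = 0.5
    seed: int = 0


@dataclass
class BaseLearner:
    """One fitted first-layer classifier at a single resolution."""

    segments: int
    replica: int
    intercept: float
    coef: np.ndarray  # (n_neurons * J,), neuron-major
    C: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.coef + self.intercept)


@dataclass
class MetaLearner:
    """Second-layer stacker over per-resolution base probabilities."""

    intercept: float
    coef: np.ndarray  # (Q,)
    C: float

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        return _sigmoid(Z @ self.coef + self.intercept)


@dataclass
class DecodingModel:
    """Fitted per-category model: bagged banks plus (optionally) a stacker."""

    category: str
    segments: tuple
    banks: dict  # segments -> list[BaseLearner] (length R)
    meta: MetaLearner | None
    n_neurons: int
    selected_C: dict  # segments -> chosen l1 C

    def base_probabilities(self, X_by_m: dict) -> np.ndarray:
        """Replica-averaged base probability per resolution: (n, Q)."""
        cols = []
        for m in self.segments:
            probs = np.mean(
                [bl.predict_proba(X_by_m[m]) for bl in self.banks[m]], axis=0
            )
            cols.append(probs)
        return np.column_stack(cols)

    def predict_proba(self, X_by_m: dict) -> np.ndarray:
        Z = self.base_probabilities(X_by_m)
        if self.meta is None:
            return Z[:, 0]
        return self.meta.predict_proba(Z)


@dataclass
class FoldModel:
    test_idx: np.ndarray
    model: DecodingModel


@dataclass
class CategoryResult:
    category: str
    y_true: np.ndarray
    oof_prob: np.ndarray
    oof_pred: np.ndarray
    folds: list
    full_model: DecodingModel | None

    @property
    def mcc(self) -> float:
        return _metrics.mcc(_metrics.confusion_counts(self.y_true, self.oof_pred))

    @property
    def informedness(self) -> float:
        return _metrics.informedness(
            _metrics.confusion_counts(self.y_true, self.oof_pred)
        )

    @property
    def markedness(self) -> float:
        return _metrics.markedness(
            _metrics.confusion_counts(self.y_true, self.oof_pred)
        )


@dataclass
class DecodingResult:
    """Out-of-fold predictions and fitted models for every category,
    together with the shared feature representation."""

    config: DecoderConfig
    category_names: tuple
    categories: list  # list[CategoryResult]
    bases: dict = field(repr=False)  # segments -> Basis
    features: dict = field(repr=False)  # segments -> (n_trials, p) matrix
    regions: tuple = ()

    def mcc_by_category(self) -> dict:
        return {c.category: c.mcc for c in self.categories}

    def mean_mcc(self) -> float:
        return float(np.mean([c.mcc for c in self.categories]))

    def metrics_table(self):
        import pandas as pd

        rows = [
            {
                "category": c.category,
                "mcc": c.mcc,
                "informedness": c.informedness,
                "markedness": c.markedness,
            }
            for c in self.categories
        ]
        return pd.DataFrame(rows)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _fit_l1_logistic(X: np.ndarray, y: np.ndarray, C: float) -> tuple[float, np.ndarray]:
    if len(np.unique(y)) < 2:
        raise ValueError("training split contains a single class")
    # large intercept_scaling leaves the intercept effectively
    # unpenalized (liblinear otherwise shrinks it with the L1 term)
    clf = LogisticRegression(
        C=C, l1_ratio=1.0, solver="liblinear", max_iter=5000, tol=1e-5,
        intercept_scaling=100.0, random_state=0,
    )
    clf.fit(X, y)
    if getattr(clf, "n_iter_", np.array([0])).max() >= 5000:
        raise RuntimeError(
            f"L1 logistic fit did not converge (C={C}, n={X.shape[0]}, "
            f"p={X.shape[1]})"
        )
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def fit_base_learner(
    X: np.ndarray, y: np.ndarray, C: float, segments: int = 1, replica: int = 0
) -> BaseLearner:
    """Fit one L1-logistic base learner on feature matrix ``X``.

    ``C`` is the inverse penalty strength; small C drives all
    coefficients to exactly zero (intercept-only model at the label base
    rate). Deterministic given the data and C.
    """
    intercept, coef = _fit_l1_logistic(X, y, C)
    return BaseLearner(
        segments=segments, replica=replica, intercept=intercept, coef=coef, C=C
    )


def _select_l1(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple,
    n_folds: int,
    seed: int,
) -> tuple[float, np.ndarray]:
    """Inner-CV selection of C by out-of-fold cross-entropy.

    Uses the one-standard-error rule: among the grid, the strongest
    penalty (smallest C) whose mean per-fold cross-entropy lies within
    one standard error of the minimum wins — the conventional choice
    for sparse models, and the one that lets fits on label-independent
    data collapse to the intercept-only model. Returns the winning C
    and the out-of-fold probabilities obtained at that C (reused as the
    stacked training column for this resolution).
    """
    grid = tuple(sorted(grid))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    fold_losses = np.empty((len(grid), len(splits)))
    oofs = []
    for gi, C in enumerate(grid):
        oof = np.empty(len(y))
        for si, (tr, va) in enumerate(splits):
            intercept, coef = _fit_l1_logistic(X[tr], y[tr], C)
            oof[va] = _sigmoid(X[va] @ coef + intercept)
            fold_losses[gi, si] = log_loss(y[va], oof[va], labels=[0, 1])
        oofs.append(oof)
    means = fold_losses.mean(axis=1)
    best = int(np.argmin(means))
    se = fold_losses[best].std(ddof=1) / np.sqrt(len(splits))
    chosen = int(np.nonzero(means <= means[best] + se)[0][0])
    return float(grid[chosen]), oofs[chosen]


def _bootstrap_indices(
    rng: np.random.Generator, y: np.ndarray, enabled: bool
) -> np.ndarray:
    n = len(y)
    if not enabled:
        return np.arange(n)
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) == 2:
            return idx
    raise RuntimeError("could not draw a two-class bootstrap resample")


def fit_bagged_bank(
    X_by_m: dict,
    y: np.ndarray,
    C_by_m: dict,
    n_replicas: int,
    seed: int,
    bootstrap: bool = True,
) -> dict:
    """Fit R bootstrap replicas of each resolution's base learner.

    Each replica is fit on a with-replacement resample of the training
    trials (shared across resolutions within a replica, so the replicas
    are coherent data views). Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    banks: dict = {m: [] for m in X_by_m}
    for r in range(n_replicas):
        idx = _bootstrap_indices(rng, y, bootstrap)
        for m, X in X_by_m.items():
            banks[m].append(
                fit_base_learner(X[idx], y[idx], C_by_m[m], segments=m, replica=r)
            )
    return banks


def fit_meta_learner(
    Z: np.ndarray,
    y: np.ndarray,
    grid: tuple,
    n_folds: int,
    seed: int,
) -> MetaLearner:
    """Fit the L1-logistic stacker on out-of-fold base probabilities."""
    if Z.ndim != 2:
        raise ValueError("stacked inputs must be 2-D (trials x resolutions)")
    C, _ = _select_l1(Z, y, grid, n_folds, seed)
    intercept, coef = _fit_l1_logistic(Z, y, C)
    return MetaLearner(intercept=intercept, coef=coef, C=C)


def _fit_on_subset(
    X_by_m: dict,
    y: np.ndarray,
    config: DecoderConfig,
    category: str,
    n_neurons: int,
    seed: int,
) -> DecodingModel:
    """Full fitting recipe on one training set: inner-CV per-resolution L1
    selection, stacking on the inner out-of-fold probabilities, then a
    final bagged bank at the selected penalties."""
    rng = np.random.default_rng(seed)
    inner_seed = int(rng.integers(_MAX_SEED))
    C_by_m, oof_cols = {}, []
    for m in config.segments:
        C, oof = _select_l1(
            X_by_m[m], y, config.l1_grid, config.inner_folds, inner_seed
        )
        C_by_m[m] = C
        oof_cols.append(oof)
    meta = None
    if config.stack:
        Z = np.column_stack(oof_cols)
        meta = fit_meta_learner(
            Z, y, config.meta_l1_grid, config.inner_folds,
            int(rng.integers(_MAX_SEED)),
        )
    banks = fit_bagged_bank(
        X_by_m, y, C_by_m, config.n_replicas, int(rng.integers(_MAX_SEED)),
        bootstrap=config.bootstrap,
    )
    return DecodingModel(
        category=category,
        segments=tuple(config.segments),
        banks=banks,
        meta=meta,
        n_neurons=n_neurons,
        selected_C=C_by_m,
    )


def compute_feature_stack(ensemble, config: DecoderConfig) -> tuple[dict, dict]:
    """Bases and per-resolution feature matrices for a whole ensemble."""
    if not config.stack and len(config.segments) != 1:
        raise ValueError("unstacked models require exactly one resolution")
    patterns = bin_patterns(ensemble, config.grid_ms)
    bases: dict[int, Basis] = {}
    feats: dict[int, np.ndarray] = {}
    for m in config.segments:
        bases[m] = build_basis(
            ensemble.window_ms, config.grid_ms, m, order=config.order
        )
        feats[m] = feature_matrix(patterns, bases[m])
    return bases, feats


def nested_cv_fit_predict(
    ensemble,
    config: DecoderConfig,
    refit_full: bool = True,
) -> DecodingResult:
    """Run the full nested-CV pipeline on one ensemble.

    For each category (one-vs-rest), stratified outer folds produce
    out-of-sample predictions for every trial; all hyperparameter
    selection and stacking happens strictly inside each outer training
    set. Optionally refits a model on all trials (``refit_full``) for
    interpretation.
    """
    bases, feats = compute_feature_stack(ensemble, config)
    n_neurons = ensemble.n_neurons
    master = np.random.default_rng(config.seed)
    categories = []
    for c, name in enumerate(ensemble.category_names):
        y = ensemble.labels[:, c].astype(int)
        if y.sum() < config.outer_folds or (len(y) - y.sum()) < config.outer_folds:
            raise ValueError(
                f"category {name!r}: too few trials per class for "
                f"{config.outer_folds} stratified outer folds"
            )
        cat_rng = np.random.default_rng(int(master.integers(_MAX_SEED)))
        skf = StratifiedKFold(
            n_splits=config.outer_folds, shuffle=True,
            random_state=int(cat_rng.integers(_MAX_SEED)),
        )
        oof_prob = np.empty(len(y))
        folds = []
        for tr, te in skf.split(feats[config.segments[0]], y):
            X_tr = {m: feats[m][tr] for m in config.segments}
            X_te = {m: feats[m][te] for m in config.segments}
            model = _fit_on_subset(
                X_tr, y[tr], config, name, n_neurons,
                int(cat_rng.integers(_MAX_SEED)),
            )
            oof_prob[te] = model.predict_proba(X_te)
            folds.append(FoldModel(test_idx=te, model=model))
        full_model = None
        if refit_full:
            full_model = _fit_on_subset(
                feats, y, config, name, n_neurons,
                int(cat_rng.integers(_MAX_SEED)),
            )
        # ties at the threshold go to the negative class (conservative)
        oof_pred = (oof_prob > config.threshold).astype(int)
        categories.append(
            CategoryResult(
                category=name,
                y_true=y,
                oof_prob=oof_prob,
                oof_pred=oof_pred,
                folds=folds,
                full_model=full_model,
            )
        )
    return DecodingResult(
        config=config,
        category_names=tuple(ensemble.category_names),
        categories=categories,
        bases=bases,
        features=feats,
        regions=tuple(ensemble.regions),
    )
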