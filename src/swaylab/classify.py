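"""Leak-free classification harness for HOA-vs-PD discrimination.

The protocol: 15 stratified 70/30 train-test splits (seeds 0..14, seed 0
the representative run).  Inside every split, mean imputation, feature
standardisation and (optionally) SMOTE oversampling are fitted on the
training partition only; three base learners (random forest, gradient
boosting, SVM) are grid-search tuned with 3-fold stratified CV maximising
ROC AUC, then combined into a soft-voting ensemble (unweighted mean of
member PD-probabilities, threshold 0.5, ties predict PD).  Per-split test
metrics are summarised with a 1000-resample percentile bootstrap.

PD is the positive class throughout; sensitivity is PD recall and
specificity is HOA recall.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .preprocess import MeanImputer
from .stats import bh_adjust

__all__ = [
    "GridSpec",
    "SplitMetrics",
    "MetricSummary",
    "RepeatedSplitsResult",
    "FeatureScaler",
    "class_imbalance_ratio",
    "stratified_split",
    "scale_train_test",
    "smote_oversample",
    "tune_model",
    "soft_vote",
    "rank_auc",
    "confusion_and_metrics",
    "run_repeated_splits",
    "bootstrap_ci",
    "summarize_metrics",
    "compare_smote_pipelines",
    "importance_concordance",
]

MODEL_NAMES = ("rf", "gb", "svm")

#: Metrics reported per model in the summary (Table-3 layout).
SUMMARY_METRICS = (
    "accuracy",
    "f1_pd",
    "f1_hoa",
    "auc",
    "sensitivity",
    "specificity",
    "precision_pd",
    "precision_hoa",
)

#: Metrics entering the SMOTE-vs-no-SMOTE paired comparison.
COMPARE_METRICS = (
    "auc",
    "accuracy",
    "f1_pd",
    "f1_hoa",
    "sensitivity",
    "specificity",
)


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grids for the three base learners.

    Keys follow scikit-learn parameter names; value lists are enumerated
    in insertion order (first key outermost), and grid-search ties are
    broken in favour of the earlier combination.
    """

    rf: dict = field(default_factory=dict)
    gb: dict = field(default_factory=dict)
    svm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in MODEL_NAMES:
            grid = getattr(self, name)
            if not grid or any(len(v) == 0 for v in grid.values()):
                raise ValueError(f"empty grid for model {name!r}")

    def for_model(self, name: str) -> dict:
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}")
        return getattr(self, name)

    @classmethod
    def full(cls) -> "GridSpec":
        """The reference tuning grids (full search space)."""
        return cls(
            rf={
                "n_estimators": [100, 150],
                "max_depth": [None, 20, 30],
                "min_samples_split": [2, 5, 10],
                "min_samples_leaf": [1, 2, 4],
            },
            gb={
                "n_estimators": [100, 150],
                "learning_rate": [0.01, 0.1, 0.15],
                "max_depth": [4, 6, 8],
                "subsample": [0.7, 0.9],
                "min_samples_split": [2, 6],
                "min_samples_leaf": [1, 3],
            },
            svm={
                "C": [1, 10, 50],
                "kernel": ["rbf", "linear", "poly"],
                "gamma": ["scale", "auto", 0.1],
                "degree": [2, 3],
            },
        )

    @classmethod
    def small(cls) -> "GridSpec":
        """Reduced grids for fast, desk-scale runs (same learners)."""
        return cls(
            rf={
                "n_estimators": [100],
                "max_depth": [None, 20],
                "min_samples_leaf": [1, 2],
            },
            gb={
                "n_estimators": [100],
                "learning_rate": [0.01, 0.1],
                "max_depth": [4],
                "subsample": [0.9],
            },
            svm={
                "C": [1, 10],
                "kernel": ["rbf", "linear"],
                "gamma": ["scale"],
            },
        )


def iter_grid(grid: dict) -> "itertools.product":
    """Enumerate parameter combinations in first-key-outermost order."""
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def build_estimator(name: str, params: dict, seed: int):
    """Instantiate a seeded base learner with the given hyperparameters."""
    if name == "rf":
        return RandomForestClassifier(**params, random_state=seed)
    if name == "gb":
        return GradientBoostingClassifier(**params, random_state=seed)
    if name == "svm":
        return SVC(**params, probability=True, random_state=seed)
    raise ValueError(f"unknown model {name!r}")


def class_imbalance_ratio(labels: np.ndarray) -> float:
    """Majority:minority class ratio, rounded to 2 decimals (37:26 -> 1.42)."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    if len(counts) != 2:
        raise ValueError("expected exactly two classes")
    return round(float(counts.max() / counts.min()), 2)


def stratified_split(
    labels: np.ndarray, test_fraction: float = 0.30, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test partition with half-up per-class test counts.

    Each class contributes ``round_half_up(n_class * test_fraction)`` test
    members, so the 37 HOA + 26 PD reference cohort yields an 11 + 8 = 19
    sample test set.  Deterministic given ``seed``; returned index arrays
    are sorted, disjoint and exhaustive.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} too small to split")
        n_test = int(np.floor(len(idx) * test_fraction + 0.5))
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


class FeatureScaler:
    """Standardisation to zero mean / unit SD, fitted on training rows.

    Features whose training SD is zero are centred only and recorded in
    ``degenerate_``.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.degenerate_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if len(X) == 0:
            raise ValueError("empty training set")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.degenerate_ = sd == 0
        self.scale_ = np.where(self.degenerate_, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def scale_train_test(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, FeatureScaler]:
    """Fit a :class:`FeatureScaler` on the training rows and apply it to both."""
    scaler = FeatureScaler().fit(X_train)
    return scaler.transform(X_train), scaler.transform(X_test), scaler


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling (SMOTE) to balanced class counts.

    Each synthetic sample is a convex combination ``x_i + u * (x_j - x_i)``
    of a minority sample and one of its ``k`` nearest minority neighbours
    (``u`` uniform on [0, 1]).  Already-balanced input is returned
    unchanged.  If the minority class has at most ``k`` members, ``k`` is
    reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    X_min = X[y == minority]
    n_min = len(X_min)
    if n_min <= k:
        warnings.warn(
            f"minority class has {n_min} samples <= k={k}; reducing k to "
            f"{n_min - 1}",
            stacklevel=2,
        )
        k = n_min - 1
    if k < 1:
        raise ValueError("minority class too small for SMOTE")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)  # col 0 is the point itself
    base = rng.integers(0, n_min, size=need)
    pick = rng.integers(1, k + 1, size=need)
    u = rng.random(size=need)
    partners = neigh[base, pick]
    synth = X_min[base] + u[:, None] * (X_min[partners] - X_min[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    return X_out, y_out


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by the rank (pairwise-comparison) method with midranks.

    Equivalent to the trapezoidal area over all thresholds.  Returns NaN
    when the truth contains a single class.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = sps.rankdata(scores)
    return float(
        (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def tune_model(
    name: str,
    grid: dict,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    use_smote: bool = False,
    smote_k: int = 5,
    n_folds: int = 3,
) -> tuple[dict, float]:
    """Exhaustive grid search maximising mean ROC AUC over stratified CV.

    All per-fold preprocessing (standardisation, optional SMOTE) is fitted
    inside each fold on that fold's training part only.  Ties are broken
    by first-in-grid enumeration order.

    Returns the best hyperparameter dict and its mean CV AUC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    folds = list(skf.split(X, y))
    for _, val_idx in folds:
        if len(np.unique(y[val_idx])) < 2:
            raise ValueError("a CV fold contains a single class")
    best_params, best_score = None, -np.inf
    for params in iter_grid(grid):
        scores = []
        for fold_i, (tr, va) in enumerate(folds):
            X_tr, X_va, _ = scale_train_test(X[tr], X[va])
            y_tr = y[tr]
            if use_smote:
                X_tr, y_tr = smote_oversample(
                    X_tr, y_tr, k=smote_k, seed=seed * n_folds + fold_i
                )
            clf = build_estimator(name, params, seed)
            clf.fit(X_tr, y_tr)
            prob = clf.predict_proba(X_va)[:, list(clf.classes_).index(1)]
            scores.append(rank_auc(y[va], prob))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    return best_params, best_score


def soft_vote(
    member_probs: np.ndarray, n_members: int | None = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-voting ensemble over member PD-probabilities.

    ``member_probs`` has shape (n_members, n_samples); the ensemble
    probability is the unweighted mean and the predicted label is PD (1)
    iff it is >= 0.5.  The member count is checked against ``n_members``
    (3 base learners by default; pass ``None`` to accept any count).
    """
    member_probs = np.atleast_2d(np.asarray(member_probs, dtype=float))
    if n_members is not None and member_probs.shape[0] != n_members:
        raise ValueError(
            f"expected {n_members} ensemble members, got "
            f"{member_probs.shape[0]}"
        )
    if np.any(member_probs < 0) or np.any(member_probs > 1):
        raise ValueError("member probabilities must lie in [0, 1]")
    prob = member_probs.mean(axis=0)
    return (prob >= 0.5).astype(int), prob


@dataclass(frozen=True)
class SplitMetrics:
    """Test-set classification metrics for one model on one split."""

    split_id: int
    model: str
    accuracy: float
    auc: float
    f1_pd: float
    f1_hoa: float
    precision_pd: float
    precision_hoa: float
    sensitivity: float  # PD recall
    specificity: float  # HOA recall
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class MetricSummary:
    """Bootstrap summary of one metric: mean and 95% percentile CI."""

    metric: str
    mean: float
    ci_low: float
    ci_high: float


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else float("nan")


def confusion_and_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    split_id: int = 0,
    model: str = "",
) -> SplitMetrics:
    """Confusion counts and derived metrics with PD (1) as positive class.

    AUC is computed from ``scores`` by the rank method (midranks for ties)
    and is NaN when the truth is single-class.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("y_true, y_pred and scores must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    prec_pd = _safe_div(tp, tp + fp)
    rec_pd = _safe_div(tp, tp + fn)
    prec_hoa = _safe_div(tn, tn + fn)
    rec_hoa = _safe_div(tn, tn + fp)
    f1_pd = _safe_div(2 * prec_pd * rec_pd, prec_pd + rec_pd)
    f1_hoa = _safe_div(2 * prec_hoa * rec_hoa, prec_hoa + rec_hoa)
    return SplitMetrics(
        split_id=split_id,
        model=model,
        accuracy=(tp + tn) / len(y_true),
        auc=rank_auc(y_true, scores),
        f1_pd=f1_pd,
        f1_hoa=f1_hoa,
        precision_pd=prec_pd,
        precision_hoa=prec_hoa,
        sensitivity=rec_pd,
        specificity=rec_hoa,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


@dataclass
class RepeatedSplitsResult:
    """Output of :func:`run_repeated_splits`.

    ``metrics`` holds one row per (split, model) including the ensemble;
    ``importances`` are the impurity feature importances of the tree
    models fitted on the representative (seed 0) split's training data;
    ``best_params`` records the tuned hyperparameters per split.
    """

    metrics: pd.DataFrame
    importances: dict[str, np.ndarray]
    best_params: list[dict[str, dict]]

    def model_metrics(self, model: str) -> pd.DataFrame:
        return self.metrics[self.metrics["model"] == model].sort_values(
            "split_id"
        )


def _split_states(table: pd.DataFrame, train_idx: np.ndarray):
    """Fit the leak-free per-split preprocessing (imputer + scaler).

    Exposed for metamorphic leakage testing: every returned state depends
    on training rows only.
    """
    feats = list(FEATURE_NAMES)
    imputer = MeanImputer().fit(table.iloc[train_idx], feats)
    filled = imputer.transform(table)
    X = filled[feats].to_numpy(dtype=float)
    scaler = FeatureScaler().fit(X[train_idx])
    return X, imputer, scaler


def run_repeated_splits(
    table: pd.DataFrame,
    grids: GridSpec | None = None,
    n_splits: int = 15,
    use_smote: bool = False,
    smote_k: int = 5,
    test_fraction: float = 0.30,
    seeds: list[int] | None = None,
) -> RepeatedSplitsResult:
    """Run the full repeated-split evaluation harness.

    For each split seed (default 0..n_splits-1): stratified 70/30 split,
    training-only imputation and standardisation, optional SMOTE, 3-fold
    grid-search tuning of RF/GB/SVM, soft-voting ensemble, and test-set
    metrics for all four models.
    """
    if grids is None:
        grids = GridSpec.full()
    if seeds is None:
        seeds = list(range(n_splits))
    if len(seeds) != n_splits:
        raise ValueError("seeds must have length n_splits")
    y = (table["group"].to_numpy() == "PD").astype(int)

    all_metrics: list[SplitMetrics] = []
    importances: dict[str, np.ndarray] = {}
    best_params_per_split: list[dict[str, dict]] = []
    for s in seeds:
        train_idx, test_idx = stratified_split(
            table["group"].to_numpy(), test_fraction, seed=s
        )
        X, _, scaler = _split_states(table, train_idx)
        X_tr, X_te = X[train_idx], X[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]

        split_best: dict[str, dict] = {}
        member_probs = []
        for name in MODEL_NAMES:
            params, _ = tune_model(
                name, grids.for_model(name), X_tr, y_tr,
                seed=s, use_smote=use_smote, smote_k=smote_k,
            )
            split_best[name] = params
            X_fit, y_fit = scaler.transform(X_tr), y_tr
            if use_smote:
                X_fit, y_fit = smote_oversample(X_fit, y_fit, k=smote_k, seed=s)
            clf = build_estimator(name, params, seed=s)
            clf.fit(X_fit, y_fit)
            prob = clf.predict_proba(scaler.transform(X_te))
            prob_pd = prob[:, list(clf.classes_).index(1)]
            member_probs.append(prob_pd)
            all_metrics.append(
                confusion_and_metrics(
                    y_te, (prob_pd >= 0.5).astype(int), prob_pd,
                    split_id=s, model=name,
                )
            )
            if s == seeds[0] and name in ("rf", "gb"):
                importances[name] = np.asarray(clf.feature_importances_)
        pred, prob = soft_vote(np.vstack(member_probs))
        all_metrics.append(
            confusion_and_metrics(y_te, pred, prob, split_id=s, model="ensemble")
        )
        best_params_per_split.append(split_best)

    metrics = pd.DataFrame([asdict(m) for m in all_metrics])
    return RepeatedSplitsResult(
        metrics=metrics,
        importances=importances,
        best_params=best_params_per_split,
    )


def bootstrap_ci(
    values: np.ndarray, B: int = 1000, seed: int = 0, metric: str = ""
) -> MetricSummary:
    """Percentile bootstrap of the mean of per-split metric values.

    ``B`` resamples with replacement (same size as the input); the summary
    mean is the observed mean and the CI is the 2.5/97.5 percentile of the
    resample means.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(B, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return MetricSummary(
        metric=metric,
        mean=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def summarize_metrics(
    metrics: pd.DataFrame, B: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Bootstrap summary table: per model, per reported metric,
    mean [95% CI] over the per-split values."""
    rows = []
    ss = np.random.SeedSequence(seed)
    models = [m for m in ("rf", "gb", "svm", "ensemble") if
              m in set(metrics["model"])]
    children = ss.spawn(len(models) * len(SUMMARY_METRICS))
    i = 0
    for model in models:
        sub = metrics[metrics["model"] == model]
        for metric in SUMMARY_METRICS:
            summ = bootstrap_ci(
                sub[metric].to_numpy(),
                B=B,
                seed=children[i].generate_state(1)[0] % (2**31),
                metric=metric,
            )
            i += 1
            rows.append(
                {
                    "model": model,
                    "metric": metric,
                    "mean": summ.mean,
                    "ci_low": summ.ci_low,
                    "ci_high": summ.ci_high,
                }
            )
    return pd.DataFrame(rows)


def compare_smote_pipelines(
    metrics_with: pd.DataFrame, metrics_without: pd.DataFrame
) -> pd.DataFrame:
    """Paired SMOTE-vs-no-SMOTE comparison per base model and metric.

    Two-sided paired Wilcoxon signed-rank tests over splits matched by
    seed, with BH FDR correction across the non-NA (model, metric) family.
    All-zero difference vectors leave the Wilcoxon statistic undefined and
    are reported as NA.
    """
    rows = []
    for model in MODEL_NAMES:
        a = metrics_with[metrics_with["model"] == model].set_index("split_id")
        b = metrics_without[metrics_without["model"] == model].set_index(
            "split_id"
        )
        if not a.index.sort_values().equals(b.index.sort_values()):
            raise ValueError("the two arms must share the same split seeds")
        b = b.loc[a.index]
        for metric in COMPARE_METRICS:
            diff = a[metric].to_numpy() - b[metric].to_numpy()
            if np.allclose(diff, 0):
                p = float("nan")
            else:
                p = float(
                    sps.wilcoxon(
                        a[metric].to_numpy(),
                        b[metric].to_numpy(),
                        alternative="two-sided",
                    ).pvalue
                )
            rows.append({"model": model, "metric": metric, "p": p})
    out = pd.DataFrame(rows)
    mask = out["p"].notna().to_numpy()
    q = np.full(len(out), np.nan)
    if mask.any():
        q[mask] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["q"] = q
    return out


#: Largest n at which the Spearman p is computed by exact permutation.
EXACT_SPEARMAN_LIMIT = 8


def importance_concordance(
    importances_a: np.ndarray, importances_b: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between two feature-importance vectors.

    Midranks for ties; exact permutation p for n <= 8, otherwise the
    t-distribution approximation.
    """
    a = np.asarray(importances_a, dtype=float)
    b = np.asarray(importances_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("importance vectors must be 1-D of equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 features")
    ra, rb = sps.rankdata(a), sps.rankdata(b)
    with np.errstate(invalid="ignore"):
        rho = float(np.corrcoef(ra, rb)[0, 1])
    if np.isnan(rho):
        return float("nan"), float("nan")
    if n <= EXACT_SPEARMAN_LIMIT:
        count = 0
        total = 0
        for perm in itertools.permutations(rb):
            r = np.corrcoef(ra, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return rho, p
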