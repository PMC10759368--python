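"""Repeated-split classifier evaluation of screening feature sets.

The evaluation design: repeatedly (default 200 times) draw a stratified
70/30 train/test partition, upsample the training set with replacement until
all classes match the majority-class frequency (never the test set), fit a
random-forest scorer per feature set on the balanced training data, and
measure test-set AUC plus Youden-thresholded accuracy metrics. All feature
sets share the identical partition within an iteration, so per-iteration AUC
differences are paired; a sign-flip permutation test on the median paired
difference compares two feature sets.

The AUC is computed by the Mann-Whitney formulation (ties half-credited):
the probability a random impaired case scores above a random unimpaired
case. The Youden threshold maximizes J = sensitivity + specificity - 1 over
the observed score values, taking the lowest threshold on ties (favoring
sensitivity, the screening use-case).

The classifier is pluggable: anything exposing ``score(X) -> P(impaired)``
via a ``classifier_factory(X, y, seed)`` callable can stand in for the
default tuned random forest, so the pipeline logic is testable with
deterministic stubs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .simulate import subscore_columns

__all__ = [
    "EvalConfig",
    "SplitMetrics",
    "RepeatedEvalSummary",
    "PermutationResult",
    "FEATURE_SET_NAMES",
    "feature_matrix",
    "stratified_split",
    "upsample_to_balance",
    "fit_classifier",
    "roc_auc",
    "youden_threshold",
    "evaluate_feature_sets",
    "paired_permutation_median_diff",
]

FEATURE_SET_NAMES = ("dcr_features", "mmse_total", "demographics", "all")

METRIC_NAMES = ("auc", "sensitivity", "specificity", "ppv", "npv",
                "balanced_accuracy", "youden_threshold")


@dataclass
class EvalConfig:
    """Knobs of the repeated-split evaluation.

    ``oob_error_floor`` doubles as the random-forest stopping tolerance on
    out-of-bag error improvement between tree-growth chunks and as the
    indifference band when selecting the smallest features-per-split value.
    """

    n_iterations: int = 200
    train_fraction: float = 0.7
    n_trees_max: int = 500
    oob_error_floor: float = 0.001
    tree_chunk: int = 100
    mtry_grid: tuple[int, ...] | None = None
    feature_sets: tuple[str, ...] = FEATURE_SET_NAMES
    seed: int = 0
    n_permutations: int = 5000

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in ("n_iterations", "n_trees_max", "tree_chunk", "n_permutations"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SplitMetrics:
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    balanced_accuracy: float
    youden_threshold: float


@dataclass(frozen=True)
class PermutationResult:
    observed_median_diff: float
    p_value: float
    n_permutations: int


@dataclass
class RepeatedEvalSummary:
    """Per-iteration metric distributions per feature set, plus summaries."""

    per_iteration: dict[str, pd.DataFrame]
    config: EvalConfig
    iteration_seeds: list[int] = field(default_factory=list)

    def aucs(self, feature_set: str) -> np.ndarray:
        return self.per_iteration[feature_set]["auc"].to_numpy()

    def summary(self) -> pd.DataFrame:
        """Median and SD of every metric per feature set (recomputable from
        the stored per-iteration tables)."""
        rows = {}
        for name, table in self.per_iteration.items():
            row = {}
            for metric in METRIC_NAMES:
                vals = table[metric].to_numpy(dtype=float)
                row[f"{metric}_median"] = float(np.nanmedian(vals))
                row[f"{metric}_sd"] = (
                    float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else float("nan")
                )
            rows[name] = row
        return pd.DataFrame.from_dict(rows, orient="index")


# -- feature sets ----------------------------------------------------------


def _encode_demographics(records: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": records["age"].to_numpy(dtype=float),
            "sex_female": (records["sex"] == "female").to_numpy(dtype=float),
            "education_years": records["education_years"].to_numpy(dtype=float),
        }
    )


def feature_matrix(records: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    """Numeric design matrix for a named feature set.

    ``dcr_features``: all age-scaled clock subscores plus the delayed-recall
    word count (no composite scores). ``mmse_total``: the MMSE total alone.
    ``demographics``: age, sex, years of education. ``all``: their union.
    """
    sub_cols = sorted(c for c in records.columns if c in set(subscore_columns(99)))
    if feature_set == "dcr_features":
        return records[sub_cols + ["delayed_recall"]].astype(float)
    if feature_set == "mmse_total":
        return records[["mmse"]].astype(float)
    if feature_set == "demographics":
        return _encode_demographics(records)
    if feature_set == "all":
        dcr = records[sub_cols + ["delayed_recall"]].astype(float)
        return pd.concat(
            [dcr, records[["mmse"]].astype(float), _encode_demographics(records)
             .set_index(dcr.index)],
            axis=1,
        )
    raise KeyError(f"unknown feature set {feature_set!r}")


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        uniq = set(np.unique(arr))
        if not uniq <= {"impaired", "unimpaired"}:
            raise ValueError(
                f"string labels must be 'impaired'/'unimpaired', got {sorted(uniq)}"
            )
        return (arr == "impaired").astype(int)
    return arr.astype(int)


# -- split / balance -------------------------------------------------------


def stratified_split(
    labels, train_fraction: float = 0.7, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive stratified partition into train/test indices.

    Within each class the train count is ``round(train_fraction * n_class)``
    clipped so both sides keep at least one record. Classes with fewer than
    two records raise.
    """
    y = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 records")
        perm = rng.permutation(idx)
        n_train = int(np.clip(round(train_fraction * len(idx)), 1, len(idx) - 1))
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def upsample_to_balance(
    labels, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Positions (into ``labels``) of a class-balanced upsampled multiset.

    Keeps every original record and appends records resampled with
    replacement from each minority class until all class counts equal the
    majority-class count. Intended for training data only.
    """
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty training set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    parts = [np.arange(len(y))]
    for cls, count in zip(classes, counts):
        if count < target:
            idx = np.flatnonzero(y == cls)
            parts.append(rng.choice(idx, size=target - count, replace=True))
    return np.concatenate(parts)


# -- classifier ------------------------------------------------------------


class RandomForestModel:
    """Tuned random forest behind the ``score`` contract."""

    def __init__(self, forest: RandomForestClassifier, oob_error: float):
        self._forest = forest
        self.oob_error_ = oob_error
        self.max_features_ = forest.max_features
        self.n_trees_ = forest.n_estimators

    def score(self, X) -> np.ndarray:
        """Probability of the impaired (positive) class per row."""
        proba = self._forest.predict_proba(np.asarray(X, dtype=float))
        pos = int(np.flatnonzero(self._forest.classes_ == 1)[0])
        return proba[:, pos]


def _grow_forest(X, y, mtry, config: EvalConfig, seed: int):
    forest = RandomForestClassifier(
        n_estimators=0,
        warm_start=True,
        oob_score=True,
        bootstrap=True,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
    )
    prev_err = math.inf
    err = math.inf
    while forest.n_estimators < config.n_trees_max:
        forest.n_estimators = min(
            forest.n_estimators + config.tree_chunk, config.n_trees_max
        )
        forest.fit(X, y)
        err = 1.0 - forest.oob_score_
        if prev_err - err < config.oob_error_floor:
            break
        prev_err = err
    return forest, err


def fit_classifier(
    X, y, config: EvalConfig = EvalConfig(), seed: int = 0
) -> RandomForestModel:
    """Fit the tuned random forest scorer.

    Trees are grown in warm-start chunks until the out-of-bag error stops
    improving by more than ``oob_error_floor`` or ``n_trees_max`` is reached.
    Candidate features-per-split values (default: 1 and round(sqrt(p)), the
    standard heuristic; override via ``mtry_grid``) are each grown that way,
    and the smallest candidate whose OOB error is within the floor of the
    best is selected — the least features compatible with the OOB rule.
    """
    X = np.asarray(X, dtype=float)
    y = _as_binary(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    p = X.shape[1]
    grid = config.mtry_grid or tuple(sorted({1, max(1, round(math.sqrt(p)))}))
    fits = []
    for mtry in grid:
        forest, err = _grow_forest(X, y, min(mtry, p), config, seed)
        fits.append((mtry, err, forest))
    best_err = min(err for _, err, _ in fits)
    for mtry, err, forest in fits:  # grid ascending -> smallest acceptable mtry
        if err <= best_err + config.oob_error_floor:
            return RandomForestModel(forest, err)
    raise AssertionError("unreachable: best fit always acceptable")


# -- metrics ---------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney statistic; ties credited 0.5.

    Equals the probability that a random positive outscores a random
    negative, with ties half-counted. Raises if only one class is present.
    """
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_threshold(scores, labels) -> tuple[float, SplitMetrics]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate cutpoints are the observed score values; prediction is
    positive when ``score >= threshold``. Ties in J resolve to the lowest
    threshold. Predictive values with an empty denominator are NaN.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold undefined: labels contain a single class")
    thresholds = np.unique(s)
    pos_sorted = np.sort(s[y == 1])
    neg_sorted = np.sort(s[y == 0])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    # J compared in exact integer arithmetic (J ∝ tp*n_neg - fp*n_pos) so
    # ties resolve to the lowest threshold without float noise.
    j_scaled = tp * n_neg - fp * n_pos
    best = int(np.argmax(j_scaled))  # first (lowest) threshold on ties
    tp_b, fp_b = int(tp[best]), int(fp[best])
    fn_b, tn_b = n_pos - tp_b, n_neg - fp_b
    ppv = tp_b / (tp_b + fp_b) if tp_b + fp_b else float("nan")
    npv = tn_b / (tn_b + fn_b) if tn_b + fn_b else float("nan")
    metrics = SplitMetrics(
        auc=roc_auc(s, y),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        ppv=float(ppv),
        npv=float(npv),
        balanced_accuracy=float((sens[best] + spec[best]) / 2.0),
        youden_threshold=float(thresholds[best]),
    )
    return float(thresholds[best]), metrics


# -- the repeated-split experiment ----------------------------------------


def evaluate_feature_sets(
    records: pd.DataFrame,
    labels,
    config: EvalConfig = EvalConfig(),
    classifier_factory: Callable[..., object] | None = None,
) -> RepeatedEvalSummary:
    """Run the full repeated-split evaluation over the configured feature sets.

    Per iteration: one stratified split shared by every feature set (paired
    design), training-set upsampling to the majority class, one classifier
    fit per feature set, and test-set metrics at the Youden threshold.
    Per-iteration seeds derive from ``config.seed`` via a spawned seed
    sequence, so the whole experiment reproduces from one integer.
    """
    y = _as_binary(labels)
    if classifier_factory is None:
        def classifier_factory(X, yy, seed):  # noqa: ANN001 - thin default
            return fit_classifier(X, yy, config, seed)

    matrices = {
        name: feature_matrix(records, name).to_numpy(dtype=float)
        for name in config.feature_sets
    }
    children = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    per_iter: dict[str, list[dict]] = {name: [] for name in config.feature_sets}
    iteration_seeds: list[int] = []
    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        fit_seed = int(child.generate_state(1)[0] % (2**31))
        iteration_seeds.append(fit_seed)
        train_idx, test_idx = stratified_split(y, config.train_fraction, rng)
        balanced = train_idx[upsample_to_balance(y[train_idx], rng)]
        for name in config.feature_sets:
            X = matrices[name]
            model = classifier_factory(X[balanced], y[balanced], fit_seed)
            test_scores = np.asarray(model.score(X[test_idx]), dtype=float)
            _, metrics = youden_threshold(test_scores, y[test_idx])
            per_iter[name].append({"iteration": it, **metrics.__dict__})
    tables = {
        name: pd.DataFrame(rows).set_index("iteration")
        for name, rows in per_iter.items()
    }
    return RepeatedEvalSummary(per_iteration=tables, config=config,
                               iteration_seeds=iteration_seeds)


def paired_permutation_median_diff(
    aucs_a, aucs_b, n_permutations: int = 5000, seed: int = 0
) -> PermutationResult:
    """Two-sided sign-flip permutation test on the median paired difference.

    The observed statistic is ``median(a - b)``; the null distribution flips
    the sign of each paired difference independently. The p-value uses the
    add-one convention ``(1 + #{|perm| >= |obs|}) / (n_permutations + 1)``,
    so its floor is ``1 / (n_permutations + 1)``.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired AUC vectors must be 1-D and equal length")
    d = a - b
    observed = float(np.median(d))
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_permutations, len(d))) * 2 - 1
    perm_stats = np.median(signs * d, axis=1)
    p = (1.0 + np.count_nonzero(np.abs(perm_stats) >= abs(observed))) / (
        n_permutations + 1.0
    )
    return PermutationResult(observed, float(p), n_permutations)
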