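"""Accuracy, stratified splitting, ROC/AUC, and jackknife comparison.

The study design this implements: a stratified 1/2–1/2 train/test split,
3-fold cross-validated grid search on the training half, accuracy on the
test half, and leave-one-out jackknife resampling of the whole procedure to
put error bars on the ML-minus-baseline accuracy difference. A difference is
declared significant only when zero lies outside ±2 jackknife standard
errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import baseline as _baseline
from .data import FR, UFR, LABELS, AssayDataset, FeatureSetSpec, extract_features, \
    enumerate_feature_sets
from .ml import ML_METHODS, MLMethodSpec, default_method_specs, predict_arm, train_arm

logger = logging.getLogger(__name__)

BASELINE = "BASELINE"

#: Positive class for confusion counts. Immaterial to accuracy; fixed for
#: reproducible report columns.
POSITIVE_CLASS = UFR


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.5
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


@dataclass(frozen=True)
class ROCResult:
    assay: str
    solvent: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    orientation: str  # "higher-is-UFR" or "lower-is-UFR"
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    """Jackknife comparison of one ML arm against the baseline."""

    feature_set: FeatureSetSpec
    method: str
    baseline_accuracy: float
    ml_accuracy: float
    accuracy_difference: float
    jackknife_se: float
    error_bar_halfwidth: float
    significant: bool
    n_replicates: int


def confusion_from_labels(
    true: np.ndarray, predicted: np.ndarray, positive: str = POSITIVE_CLASS
) -> ConfusionCounts:
    t = np.asarray(true) == positive
    p = np.asarray(predicted) == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy of zero evaluated samples")
    return (counts.tp + counts.tn) / counts.total


def stratified_split(
    dataset: AssayDataset, config: SplitConfig
) -> tuple[AssayDataset, AssayDataset]:
    """Disjoint, exhaustive per-label split; ceil(fraction·n) goes to train."""
    counts = dataset.label_counts()
    for label in LABELS:
        if counts.get(label, 0) == 0:
            raise ValueError(f"dataset contains no {label} samples")
    rng = np.random.default_rng(config.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in LABELS:
        idx = np.array([i for i, s in enumerate(dataset.samples) if s.label == label])
        idx = idx[rng.permutation(idx.size)]
        n_train = math.ceil(config.train_fraction * idx.size)
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return (
        dataset.subset(sorted(train_idx), provenance=dataset.provenance + " [train]"),
        dataset.subset(sorted(test_idx), provenance=dataset.provenance + " [test]"),
    )


def roc_curve(dataset: AssayDataset, assay: str, solvent: str) -> ROCResult:
    """ROC from sweeping every distinct observed value as a threshold.

    Orientation (which tail of the assay indicates UFR) is auto-selected so
    the reported AUC is >= 0.5 and recorded. A constant feature yields the
    chance diagonal (AUC 0.5) with the degenerate flag set.
    """
    values = dataset.column(assay, solvent)
    labels = dataset.labels()
    pos = labels == POSITIVE_CLASS
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both labels must be present for a ROC sweep")

    if np.ptp(values) == 0:
        one = np.array([values[0]])
        return ROCResult(
            assay=assay,
            solvent=solvent,
            thresholds=one,
            tpr=np.array([0.0, 1.0]),
            fpr=np.array([0.0, 1.0]),
            auc=0.5,
            orientation="higher-is-UFR",
            degenerate=True,
        )

    def _sweep(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        # predict positive when score >= threshold; thresholds descend from
        # above the max so the curve runs (0,0) -> (1,1)
        thresholds = np.unique(scores)[::-1]
        tpr = [0.0]
        fpr = [0.0]
        for t in thresholds:
            pred = scores >= t
            tpr.append(float(np.sum(pred & pos)) / n_pos)
            fpr.append(float(np.sum(pred & ~pos)) / n_neg)
        tpr_a, fpr_a = np.array(tpr), np.array(fpr)
        return thresholds, tpr_a, fpr_a, float(np.trapezoid(tpr_a, fpr_a))

    thr_hi, tpr_hi, fpr_hi, auc_hi = _sweep(values)
    if auc_hi >= 0.5:
        return ROCResult(assay, solvent, thr_hi, tpr_hi, fpr_hi, auc_hi, "higher-is-UFR")
    thr_lo, tpr_lo, fpr_lo, auc_lo = _sweep(-values)
    return ROCResult(assay, solvent, -thr_lo, tpr_lo, fpr_lo, auc_lo, "lower-is-UFR")


def jackknife_from_estimates(estimates: np.ndarray) -> tuple[float, float]:
    """Point estimate (mean) and jackknife SE from leave-one-out estimates.

    SE = sqrt((n−1)/n · Σ(θᵢ − θ̄)²); applied to the leave-one-out means of
    a plain sample this reduces exactly to s/√n.
    """
    theta = np.asarray(estimates, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("need at least 2 leave-one-out estimates")
    mean = float(theta.mean())
    se = float(np.sqrt((n - 1) / n * np.sum((theta - mean) ** 2)))
    return mean, se


def _fit_and_score_baseline(
    train: AssayDataset, test: AssayDataset, spec: FeatureSetSpec, fit_on: str
) -> float:
    fit_ds = test if fit_on == "test" else train
    Xf, yf = extract_features(fit_ds, spec)
    model = _baseline.fit_gaussian(Xf, yf, spec)
    Xt, yt = extract_features(test, spec)
    pred = _baseline.predict(model, Xt)
    return accuracy(confusion_from_labels(yt, pred))


def _fit_and_score_arm(
    train: AssayDataset,
    test: AssayDataset,
    spec: FeatureSetSpec,
    mspec: MLMethodSpec,
    cv_folds: int,
) -> float:
    Xtr, ytr = extract_features(train, spec)
    arm = train_arm(mspec, Xtr, ytr, cv_folds=cv_folds)
    Xt, yt = extract_features(test, spec)
    pred = predict_arm(arm, Xt)
    return accuracy(confusion_from_labels(yt, pred))


def evaluate_once(
    dataset: AssayDataset,
    spec: FeatureSetSpec,
    method: str,
    config: SplitConfig,
    *,
    method_specs: dict[str, MLMethodSpec] | None = None,
    fit_on: str = "train",
) -> float:
    """Split, fit one classifier, and score accuracy on the test half.

    ``method`` is ``'BASELINE'`` or one of LR/SVM/RF/KNN. The split depends
    only on (dataset, config), so baseline and ML arms evaluated with the
    same seed share the identical split.
    """
    train, test = stratified_split(dataset, config)
    if method == BASELINE:
        return _fit_and_score_baseline(train, test, spec, fit_on)
    if method not in ML_METHODS:
        raise ValueError(f"unknown method {method!r}")
    specs = method_specs or default_method_specs(seed=config.seed)
    mspec = specs[method]
    if mspec.seed != config.seed:
        mspec = MLMethodSpec(mspec.method, mspec.grid, mspec.standardize, config.seed)
    return _fit_and_score_arm(train, test, spec, mspec, config.cv_folds)


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Independent, reproducible per-replicate seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def _jackknife_accuracies(
    dataset: AssayDataset,
    spec: FeatureSetSpec,
    methods: tuple[str, ...],
    config: SplitConfig,
    method_specs: dict[str, MLMethodSpec] | None,
    fit_on: str,
) -> dict[str, np.ndarray]:
    """Leave-one-out accuracies per method; each replicate re-optimizes on
    a shared split (drop sample i, split, fit every method, score)."""
    n = len(dataset)
    if n < 10:
        raise ValueError(f"jackknife needs n >= 10 samples, got {n}")
    out = {m: np.empty(n) for m in (BASELINE,) + tuple(m for m in methods if m != BASELINE)}
    base_specs = method_specs or default_method_specs(seed=config.seed)
    for i in range(n):
        reduced = dataset.subset([j for j in range(n) if j != i])
        rseed = replicate_seed(config.seed, i)
        train, test = stratified_split(
            reduced, SplitConfig(config.train_fraction, config.cv_folds, rseed)
        )
        out[BASELINE][i] = _fit_and_score_baseline(train, test, spec, fit_on)
        for m in methods:
            if m == BASELINE:
                continue
            ms = base_specs[m]
            ms = MLMethodSpec(ms.method, ms.grid, ms.standardize, rseed)
            out[m][i] = _fit_and_score_arm(train, test, spec, ms, config.cv_folds)
    return out


def jackknife_compare(
    dataset: AssayDataset,
    spec: FeatureSetSpec,
    method: str,
    config: SplitConfig,
    *,
    method_specs: dict[str, MLMethodSpec] | None = None,
    error_bar_multiplier: float = 2.0,
    fit_on: str = "train",
) -> ComparisonResult:
    """Leave-one-out jackknife of the ML-minus-baseline accuracy difference.

    Each replicate drops one sample, re-splits with a replicate-derived
    seed, re-optimizes both classifiers on the shared split, and records the
    accuracy difference. ``method='BASELINE'`` compares the baseline with
    itself (zero difference by construction).
    """
    accs = _jackknife_accuracies(
        dataset, spec, (method,), config, method_specs, fit_on
    )
    ml = accs[method] if method != BASELINE else accs[BASELINE]
    return _assemble_comparison(
        spec, method, accs[BASELINE], ml, error_bar_multiplier
    )


def _assemble_comparison(
    spec: FeatureSetSpec,
    method: str,
    base_acc: np.ndarray,
    ml_acc: np.ndarray,
    error_bar_multiplier: float,
) -> ComparisonResult:
    diff_mean, diff_se = jackknife_from_estimates(ml_acc - base_acc)
    halfwidth = error_bar_multiplier * diff_se
    return ComparisonResult(
        feature_set=spec,
        method=method,
        baseline_accuracy=float(base_acc.mean()),
        ml_accuracy=float(ml_acc.mean()),
        accuracy_difference=diff_mean,
        jackknife_se=diff_se,
        error_bar_halfwidth=halfwidth,
        significant=bool(abs(diff_mean) > halfwidth),
        n_replicates=base_acc.size,
    )


def run_full_comparison(
    dataset: AssayDataset,
    config: SplitConfig,
    *,
    methods: tuple[str, ...] = ML_METHODS,
    method_specs: dict[str, MLMethodSpec] | None = None,
    error_bar_multiplier: float = 2.0,
    fit_on: str = "train",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Every feature set × every ML method, with jackknife error bars.

    Returns (comparisons, baselines): 21×len(methods) comparison rows and 21
    baseline rows (jackknife mean accuracy and SE). One shared jackknife
    loop per feature set re-optimizes the baseline and all arms on identical
    splits.
    """
    comparisons = []
    baselines = []
    specs = enumerate_feature_sets()
    for k, spec in enumerate(specs):
        logger.info("feature set %d/%d: %s", k + 1, len(specs), spec.describe())
        accs = _jackknife_accuracies(
            dataset, spec, tuple(methods), config, method_specs, fit_on
        )
        b_mean, b_se = jackknife_from_estimates(accs[BASELINE])
        baselines.append(
            {
                "feature_set": spec.describe(),
                "assays": "+".join(spec.assays),
                "solvent_scope": spec.solvent_scope,
                "accuracy": b_mean,
                "jackknife_se": b_se,
                "n_replicates": len(dataset),
            }
        )
        for m in methods:
            res = _assemble_comparison(
                spec, m, accs[BASELINE], accs[m], error_bar_multiplier
            )
            comparisons.append(
                {
                    "feature_set": spec.describe(),
                    "assays": "+".join(spec.assays),
                    "solvent_scope": spec.solvent_scope,
                    "method": m,
                    "baseline_accuracy": res.baseline_accuracy,
                    "ml_accuracy": res.ml_accuracy,
                    "accuracy_difference": res.accuracy_difference,
                    "jackknife_se": res.jackknife_se,
                    "error_bar_halfwidth": res.error_bar_halfwidth,
                    "significant": res.significant,
                    "n_replicates": res.n_replicates,
                }
            )
    return pd.DataFrame(comparisons), pd.DataFrame(baselines)


def count_scheduled_optimizations(
    dataset_size: int, n_feature_sets: int, n_methods: int
) -> int:
    """Leave-one-out replicates × feature sets × ML methods."""
    if min(dataset_size, n_feature_sets, n_methods) < 0:
        raise ValueError("arguments must be non-negative")
    return dataset_size * n_feature_sets * n_methods
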