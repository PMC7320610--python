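"""Leave-one-chromosome-out evaluation, metrics, cautious classification,
recurrence-threshold sweeps and class-conditional distribution tests.

Pooled-over-folds metrics are primary: every autosomal example is scored
exactly once (when its chromosome is held out) and the pooled predictions
form the headline confusion matrix.  Per-fold metrics are also reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import features as feat
from . import model as mdl
from .dataset import (
    ConfigError,
    DatasetConfig,
    DegenerateDataError,
    Fold,
    LabeledDataset,
    balanced_subsample_idx,
    build_dataset,
    make_loco_folds,
)

# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


def compute_metrics(cc: ConfusionCounts) -> dict:
    """Sensitivity, specificity, balanced accuracy, MCC and PPV.

    A metric whose denominator is zero is reported as None (missing), never
    as 0."""
    if cc.total == 0:
        raise DegenerateDataError("all confusion counts are zero")
    tp, fp, tn, fn = cc.tp, cc.fp, cc.tn, cc.fn
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    bal = (sens + spec) / 2 if sens is not None and spec is not None else None
    ppv = tp / (tp + fp) if tp + fp else None
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": bal,
        "mcc": mcc,
        "ppv": ppv,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted 1/2 (Mann-Whitney formulation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("AUC needs both classes")
    return float(roc_auc_score((labels == 1).astype(int), scores))


# ---------------------------------------------------------------------------
# Cautious classification
# ---------------------------------------------------------------------------


@dataclass
class CautiousConfig:
    """Confidence cutoff for cautious classification.

    Confidence is the score's distance from the 0.5 decision boundary,
    thresholded symmetrically: an example is predicted with high confidence
    iff its score is >= tau or <= 1 - tau."""

    tau: float = 0.91

    def __post_init__(self):
        if not 0.5 < self.tau <= 1.0:
            raise ConfigError(f"tau must lie in (0.5, 1], got {self.tau}")


def cautious_apply(
    scores: np.ndarray, cfg: CautiousConfig
) -> tuple[np.ndarray, np.ndarray, float]:
    """Labels (+1/-1 at the 0.5 threshold), high-confidence flags, and
    coverage = fraction of examples flagged confident."""
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    labels = mdl.predict_label(scores)
    confident = (scores >= cfg.tau) | (scores <= 1.0 - cfg.tau)
    coverage = float(confident.mean()) if scores.size else 0.0
    return labels, confident, coverage


# ---------------------------------------------------------------------------
# LOCO orchestration
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    test_chrom: str
    model: mdl.TrainedModel
    test_idx: np.ndarray
    scores: np.ndarray
    metrics: dict


@dataclass
class EvalReport:
    """Pooled and per-fold LOCO results."""

    metrics: dict                   # pooled over all scored test examples
    auc: float | None
    per_fold: list[FoldResult]
    pooled_scores: np.ndarray       # aligned to pooled_idx
    pooled_idx: np.ndarray          # dataset row index of each pooled score
    pooled_labels: np.ndarray       # true labels for the pooled rows
    cautious: dict | None = None    # metrics over confident examples
    coverage: float | None = None
    skipped_folds: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        out = {"pooled": self.metrics, "auc": self.auc}
        if self.cautious is not None:
            out["cautious"] = self.cautious
            out["coverage"] = self.coverage
        out["per_fold"] = {
            fr.test_chrom: fr.metrics for fr in self.per_fold
        }
        return out


def fit_fold(
    ds: LabeledDataset,
    groups: Mapping[str, feat.FeatureGroupMatrix],
    selected: Sequence[str],
    fold: Fold,
    model_cfg: mdl.KernelModelConfig,
    n_per_class: int,
    seed: int,
    impute_policy: str = "train_mean",
) -> tuple[mdl.TrainedModel, np.ndarray]:
    """Fit one LOCO fold and score its held-out rows.

    The training side is balanced-subsampled; imputation and standardization
    statistics come from the subsampled training rows only.
    """
    sub = balanced_subsample_idx(ds.labels[fold.train_idx], n_per_class, seed)
    train_rows = fold.train_idx[sub]
    X, _ = feat.assemble(groups, selected, train_rows=train_rows,
                         impute_policy=impute_policy)
    model = mdl.fit(X[train_rows], ds.labels[train_rows], model_cfg)
    scores = mdl.predict_score(model, X[fold.test_idx])
    return model, scores


def run_loco(
    ds: LabeledDataset,
    groups: Mapping[str, feat.FeatureGroupMatrix],
    selected: Sequence[str],
    model_cfg: mdl.KernelModelConfig | None = None,
    cautious_cfg: CautiousConfig | None = None,
    n_per_class: int | None = None,
    seed: int = 0,
) -> EvalReport:
    """Full leave-one-chromosome-out evaluation.

    Each autosome is held out once; training uses balanced subsamples of the
    remaining autosomes; all held-out examples are scored.  Degenerate folds
    (empty or single-class training side) are skipped and reported.
    """
    model_cfg = model_cfg or mdl.KernelModelConfig()
    if n_per_class is None:
        n_per_class = ds.config.n_per_class
    folds = make_loco_folds(ds)
    per_fold: list[FoldResult] = []
    skipped: list[str] = []
    for k, fold in enumerate(folds):
        train_labels = ds.labels[fold.train_idx]
        if fold.degenerate or len(np.unique(train_labels)) < 2:
            warnings.warn(f"skipping degenerate fold {fold.test_chrom}")
            skipped.append(fold.test_chrom)
            continue
        model, scores = fit_fold(
            ds, groups, selected, fold, model_cfg,
            n_per_class=n_per_class, seed=seed + k,
        )
        y_test = ds.labels[fold.test_idx]
        fold_metrics = compute_metrics(
            ConfusionCounts.from_labels(y_test, mdl.predict_label(scores))
        )
        per_fold.append(FoldResult(fold.test_chrom, model, fold.test_idx, scores, fold_metrics))
    if not per_fold:
        raise DegenerateDataError("every LOCO fold was degenerate")

    pooled_idx = np.concatenate([fr.test_idx for fr in per_fold])
    pooled_scores = np.concatenate([fr.scores for fr in per_fold])
    pooled_labels = ds.labels[pooled_idx]
    pooled_metrics = compute_metrics(
        ConfusionCounts.from_labels(pooled_labels, mdl.predict_label(pooled_scores))
    )
    try:
        auc = roc_auc(pooled_scores, pooled_labels)
    except DegenerateDataError:
        auc = None

    cautious = coverage = None
    if cautious_cfg is not None:
        labels, confident, coverage = cautious_apply(pooled_scores, cautious_cfg)
        if confident.any():
            cautious = compute_metrics(
                ConfusionCounts.from_labels(pooled_labels[confident], labels[confident])
            )
        else:
            cautious = None
    return EvalReport(
        metrics=pooled_metrics,
        auc=auc,
        per_fold=per_fold,
        pooled_scores=pooled_scores,
        pooled_idx=pooled_idx,
        pooled_labels=pooled_labels,
        cautious=cautious,
        coverage=coverage,
        skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# Recurrence-threshold sweep
# ---------------------------------------------------------------------------


def recurrence_sweep(
    catalog: Sequence,
    rhos: Sequence[int],
    base_cfg: DatasetConfig,
    feature_builder,
    selected: Sequence[str],
    model_cfg: mdl.KernelModelConfig | None = None,
    n_per_class: int | None = None,
    seed: int = 0,
    min_per_class: int = 2,
) -> list[tuple[int, float | None]]:
    """Balanced accuracy of the full pipeline at each recurrence threshold.

    For each rho the catalog is relabeled, window-matched, folded and run
    through LOCO; features are recomputed per relabeled dataset through
    ``feature_builder(variants) -> groups dict``.  A rho that leaves fewer
    than ``min_per_class`` examples in either class yields a missing entry.
    """
    if sorted(rhos) != list(rhos) or any(r < 2 for r in rhos):
        raise ConfigError("rho values must be >= 2 and ascending")
    out: list[tuple[int, float | None]] = []
    for rho in rhos:
        cfg = DatasetConfig(
            region_mode=base_cfg.region_mode, rho=rho, window=base_cfg.window,
            n_per_class=base_cfg.n_per_class, seed=base_cfg.seed,
        )
        ds = build_dataset(list(catalog), cfg)
        n_pos = int(np.sum(ds.labels == 1))
        n_neg = int(np.sum(ds.labels == -1))
        if n_pos < min_per_class or n_neg < min_per_class:
            out.append((rho, None))
            continue
        groups = feature_builder(ds.variants)
        try:
            report = run_loco(
                ds, groups, selected, model_cfg,
                n_per_class=n_per_class, seed=seed,
            )
        except DegenerateDataError:
            out.append((rho, None))
            continue
        out.append((rho, report.metrics["balanced_accuracy"]))
    return out


# ---------------------------------------------------------------------------
# Distribution tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistTestResult:
    statistic: float
    pvalue: float            # scipy p-value, may underflow to 0.0
    log10_p_bound: float     # analytic upper bound on log10 p
    bound_str: str           # e.g. "< 1e-18"; equals the p-value string when representable

    @property
    def p_bound(self) -> float:
        """Numeric upper bound on the p-value (never exactly 0)."""
        if self.pvalue > 0:
            return min(self.pvalue, 10.0 ** min(self.log10_p_bound, 0.0))
        val = 10.0 ** self.log10_p_bound
        return val if val > 0.0 else 5e-324  # bound below float range


def distribution_test(values_a, values_b, method: str = "ks") -> DistTestResult:
    """Two-sample test of whether two feature cohorts share a distribution.

    Default is the two-sample Kolmogorov–Smirnov test; "mannwhitney" selects
    the Mann–Whitney U test.  p-values below the representable floor are
    reported as an explicit upper bound ("< 1e-…"), never as 0: for KS the
    bound is the one-sided tail inequality p <= 2 exp(-2 D^2 n m / (n + m)).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("both samples must be non-empty")
    if method == "ks":
        res = stats.ks_2samp(a, b, method="asymp" if min(a.size, b.size) > 50 else "auto")
        d = float(res.statistic)
        n_eff = a.size * b.size / (a.size + b.size)
        log10_bound = (math.log(2) - 2.0 * d * d * n_eff) / math.log(10)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        p = float(res.pvalue)
        log10_bound = math.log10(p) if p > 0 else -320.0
    else:
        raise ConfigError(f"unknown method {method!r}")
    p = float(res.pvalue)
    log10_bound = min(log10_bound, math.log10(p) if p > 0 else 0.0)
    if p > 0 and p >= 1e-300:
        bound_str = f"{p:.3g}"
    else:
        bound_str = f"< 1e{math.ceil(log10_bound)}"
    return DistTestResult(float(res.statistic), p, log10_bound, bound_str)
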