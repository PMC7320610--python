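"""Greedy forward selection over feature groups.

Singleton groups are first ranked by cross-validated balanced accuracy;
starting from the top-ranked group, each round evaluates adding every
remaining group (as one concatenated kernel) under the same fold partition
and training subsamples, and accepts the best addition only when it
improves balanced accuracy *significantly*.  Three stop rules are
available:

``example_permutation`` (default)
    A paired sign-flip permutation test on the pooled held-out predictions:
    each example contributes 1/(2 n_class) to balanced accuracy, the paired
    contributions of the two models are differenced, aggregated within
    genomic blocks (nearby variants share feature windows and are not
    independent), and block sums are sign-flipped to build the null.
    Candidate evaluations are averaged over several training subsamples to
    damp training-side noise.  Tested at alpha with a Bonferroni correction
    for the number of candidates in the round.  This rule stays usable and
    approximately calibrated even with very few folds.
``stderr``
    Accept when the mean per-fold paired improvement exceeds one standard
    error of the per-fold differences.
``fold_permutation``
    Sign-flip permutation over the per-fold paired differences at alpha
    (requires enough folds to be able to reject at all: with f folds the
    smallest attainable p-value is 2^-f).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import evaluation as ev
from . import features as feat
from . import model as mdl
from .dataset import ConfigError, LabeledDataset


@dataclass
class CandidateEval:
    """One candidate group set evaluated under LOCO.

    Evaluation is averaged over ``n_repeats`` balanced training subsamples
    (same folds, different subsample draws) to damp training-side noise;
    ``correct`` holds each pooled test example's mean correctness over the
    repeats, in dataset row order."""

    groups: tuple[str, ...]
    per_fold: dict[str, float]        # test chromosome -> mean balanced accuracy
    mean_bal_acc: float               # mean over folds (and repeats)
    pooled_bal_acc: float             # mean over repeats of pooled balanced accuracy
    correct: np.ndarray               # per-example mean correctness, row order
    labels: np.ndarray                # true labels, row order


@dataclass
class SelectionStep:
    candidate: str
    group_set: tuple[str, ...]
    per_fold: dict[str, float]
    mean_bal_acc: float
    pooled_bal_acc: float
    p_value: float | None
    accepted: bool


@dataclass
class SelectionTrace:
    ranking: list[tuple[str, float]]
    steps: list[SelectionStep] = field(default_factory=list)
    stopping_reason: str = ""
    selected: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "ranking": [[g, a] for g, a in self.ranking],
            "steps": [
                {
                    "candidate": s.candidate,
                    "group_set": list(s.group_set),
                    "per_fold": s.per_fold,
                    "mean_balanced_accuracy": s.mean_bal_acc,
                    "pooled_balanced_accuracy": s.pooled_bal_acc,
                    "p_value": s.p_value,
                    "accepted": s.accepted,
                }
                for s in self.steps
            ],
            "stopping_reason": self.stopping_reason,
            "selected": list(self.selected),
        }


#: Seed stride between evaluation repeats (arbitrary prime).
_REPEAT_STRIDE = 7919


def _evaluate(
    ds: LabeledDataset,
    groups: Mapping[str, feat.FeatureGroupMatrix],
    group_set: Sequence[str],
    model_cfg: mdl.KernelModelConfig,
    n_per_class: int | None,
    seed: int,
    n_repeats: int = 3,
) -> CandidateEval:
    per_fold_acc: dict[str, list[float]] = {}
    pooled_accs: list[float] = []
    correct_sum = np.zeros(len(ds))
    labels_row = np.zeros(len(ds), dtype=int)
    for rep in range(n_repeats):
        report = ev.run_loco(
            ds, groups, list(group_set), model_cfg,
            n_per_class=n_per_class, seed=seed + rep * _REPEAT_STRIDE,
        )
        for fr in report.per_fold:
            if fr.metrics["balanced_accuracy"] is not None:
                per_fold_acc.setdefault(fr.test_chrom, []).append(
                    fr.metrics["balanced_accuracy"]
                )
        pooled_accs.append(report.metrics["balanced_accuracy"])
        pred = mdl.predict_label(report.pooled_scores)
        labels_row[report.pooled_idx] = report.pooled_labels
        correct_sum[report.pooled_idx] += (pred == report.pooled_labels)
    per_fold = {c: float(np.mean(v)) for c, v in per_fold_acc.items()}
    mean_ba = float(np.mean(list(per_fold.values()))) if per_fold else float("nan")
    return CandidateEval(
        tuple(group_set), per_fold, mean_ba,
        float(np.mean(pooled_accs)), correct_sum / n_repeats, labels_row,
    )


def rank_singletons(
    ds: LabeledDataset,
    groups: Mapping[str, feat.FeatureGroupMatrix],
    model_cfg: mdl.KernelModelConfig | None = None,
    n_per_class: int | None = None,
    seed: int = 0,
    n_repeats: int = 3,
) -> list[tuple[str, float]]:
    """Rank each group alone by mean cross-validated balanced accuracy.

    Ties break by group name; a group whose matrix is entirely missing is
    ranked last."""
    model_cfg = model_cfg or mdl.KernelModelConfig()
    scored: list[tuple[str, float]] = []
    for name in sorted(groups):
        if np.isnan(groups[name].X).all():
            scored.append((name, float("-inf")))
            continue
        res = _evaluate(ds, groups, [name], model_cfg, n_per_class, seed, n_repeats)
        scored.append((name, res.mean_bal_acc))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [(g, (a if np.isfinite(a) else float("nan"))) for g, a in scored]


# ---------------------------------------------------------------------------
# Stop rules
# ---------------------------------------------------------------------------


def _balacc_contributions(y_true: np.ndarray, correct: np.ndarray) -> np.ndarray:
    """Per-example contributions whose sum is the balanced accuracy."""
    w = np.empty(len(y_true))
    for cls in (-1, 1):
        m = y_true == cls
        w[m] = 1.0 / (2.0 * m.sum())
    return w * correct


def _example_permutation_p(
    current: CandidateEval, cand: CandidateEval, blocks: np.ndarray,
    rng: np.random.Generator, n_permutations: int = 999,
) -> float:
    """One-sided p for "candidate beats current" via paired sign flips on
    pooled balanced-accuracy contributions (mean correctness over the
    evaluation repeats).

    Differences are aggregated within genomic blocks before sign-flipping:
    nearby variants share feature windows (mutation density, GC,
    conservation bins), so their paired differences are dependent, and
    flipping them independently would understate the p-value."""
    scored = current.labels != 0
    y = current.labels[scored]
    d = (_balacc_contributions(y, cand.correct[scored])
         - _balacc_contributions(y, current.correct[scored]))
    block_ids = blocks[scored]
    uniq, inv = np.unique(block_ids, return_inverse=True)
    block_sums = np.zeros(len(uniq))
    np.add.at(block_sums, inv, d)
    observed = block_sums.sum()
    nz = block_sums[block_sums != 0]
    if nz.size == 0:
        return 1.0
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, nz.size))
    null = (signs * nz).sum(axis=1)
    return float((1 + np.sum(null >= observed)) / (n_permutations + 1))


def _block_ids(ds: LabeledDataset, block_span: int) -> np.ndarray:
    """Genomic block label per dataset row (chromosome x position bin)."""
    return np.array([f"{v.chrom}:{v.pos // block_span}" for v in ds.variants])


def _paired_fold_diffs(current: CandidateEval, cand: CandidateEval) -> np.ndarray:
    common = sorted(set(current.per_fold) & set(cand.per_fold))
    return np.array([cand.per_fold[c] - current.per_fold[c] for c in common])


def _stderr_accepts(current: CandidateEval, cand: CandidateEval) -> tuple[bool, None]:
    d = _paired_fold_diffs(current, cand)
    if d.size == 0:
        return False, None
    se = d.std(ddof=1) / np.sqrt(d.size) if d.size > 1 else float("inf")
    return bool(d.mean() > se), None


def _fold_permutation_p(
    current: CandidateEval, cand: CandidateEval, rng: np.random.Generator,
) -> float:
    d = _paired_fold_diffs(current, cand)
    if d.size == 0:
        return 1.0
    if d.size <= 12:  # exact enumeration of all sign patterns
        signs = np.array(
            [[1 if (i >> j) & 1 else -1 for j in range(d.size)] for i in range(2 ** d.size)]
        )
    else:
        signs = rng.choice([-1, 1], size=(4096, d.size))
    null = (signs * d).sum(axis=1)
    return float(np.mean(null >= d.sum()))


STOP_RULES = ("example_permutation", "stderr", "fold_permutation")


def forward_select(
    ds: LabeledDataset,
    groups: Mapping[str, feat.FeatureGroupMatrix],
    model_cfg: mdl.KernelModelConfig | None = None,
    stop_rule: str = "example_permutation",
    alpha: float = 0.05,
    n_per_class: int | None = None,
    seed: int = 0,
    n_permutations: int = 999,
    n_repeats: int = 3,
    block_span: int = 10_000,
) -> tuple[tuple[str, ...], SelectionTrace]:
    """Greedy forward selection starting from the top-ranked singleton.

    All candidates within a round are evaluated under the same folds and
    training subsamples (the evaluation seed is shared), so comparisons are
    paired.  Permutation-based rules apply a Bonferroni correction for the
    number of candidates in the round.
    """
    if stop_rule not in STOP_RULES:
        raise ConfigError(f"stop_rule must be one of {STOP_RULES}")
    model_cfg = model_cfg or mdl.KernelModelConfig()
    rng = np.random.default_rng(seed)
    blocks = _block_ids(ds, block_span)

    ranking = rank_singletons(ds, groups, model_cfg, n_per_class, seed, n_repeats)
    trace = SelectionTrace(ranking=ranking)
    best_name = ranking[0][0]
    current = _evaluate(ds, groups, [best_name], model_cfg, n_per_class, seed, n_repeats)
    trace.steps.append(
        SelectionStep(best_name, current.groups, current.per_fold,
                      current.mean_bal_acc, current.pooled_bal_acc, None, True)
    )
    remaining = [g for g, _ in ranking[1:]]

    while remaining:
        candidates = []
        for name in remaining:
            cand = _evaluate(
                ds, groups, list(current.groups) + [name],
                model_cfg, n_per_class, seed, n_repeats,
            )
            candidates.append((name, cand))
        # best candidate this round; ties break by group name
        candidates.sort(key=lambda t: (-t[1].mean_bal_acc, t[0]))
        name, cand = candidates[0]

        improved = cand.mean_bal_acc > current.mean_bal_acc
        p: float | None = None
        if stop_rule == "stderr":
            accepted, _ = _stderr_accepts(current, cand)
            accepted = accepted and improved
        else:
            corrected_alpha = alpha / len(candidates)
            if stop_rule == "example_permutation":
                p = _example_permutation_p(current, cand, blocks, rng, n_permutations)
            else:
                p = _fold_permutation_p(current, cand, rng)
            accepted = improved and p <= corrected_alpha

        trace.steps.append(
            SelectionStep(name, cand.groups, cand.per_fold,
                          cand.mean_bal_acc, cand.pooled_bal_acc, p, accepted)
        )
        if not accepted:
            trace.stopping_reason = "no significant improvement"
            break
        current = cand
        remaining.remove(name)
    else:
        trace.stopping_reason = "all groups selected"

    trace.selected = current.groups
    return current.groups, trace
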