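"""Labeled driver/passenger dataset construction.

Somatic SNVs observed at least ρ times across samples form the positive
(putative driver) class; singletons (r = 1) lying within w nucleotides of a
positive on the same chromosome form the negative (putative passenger)
class.  Variants with intermediate recurrence (1 < r < ρ) are excluded from
training but kept aside so that relabeling at other thresholds does not
require re-reading inputs.  Model validation uses leave-one-chromosome-out
folds over the autosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

_NUCS = frozenset("ACGT")


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration."""


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested operation."""


@dataclass(frozen=True)
class Variant:
    """A somatic single-nucleotide substitution.

    Attributes
    ----------
    chrom : chromosome name (normalized, e.g. "chr7")
    pos : 1-based position
    ref, alt : single nucleotides, ref != alt
    r : recurrence count (times observed across samples), >= 1
    region : "coding", "noncoding" or "unassigned"
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    r: int = 1
    region: str = "unassigned"

    def __post_init__(self):
        if self.ref not in _NUCS or self.alt not in _NUCS:
            raise ValueError(f"ref/alt must be single nucleotides, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref == alt is not a variant")
        if self.r < 1:
            raise ValueError(f"recurrence must be >= 1, got {self.r}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")


#: Region-mode defaults: (recurrence threshold rho, matching window w).
REGION_DEFAULTS = {"coding": (7, 10_000), "noncoding": (8, 1_000)}


@dataclass
class DatasetConfig:
    """Labeling configuration.

    When ``rho`` or ``window`` is None the region-mode default applies:
    rho=7, w=10 000 for coding; rho=8, w=1000 for non-coding.
    """

    region_mode: str = "noncoding"
    rho: int | None = None
    window: int | None = None
    n_per_class: int = 4000
    seed: int = 0

    def __post_init__(self):
        if self.region_mode not in REGION_DEFAULTS:
            raise ConfigError(f"region_mode must be coding|noncoding, got {self.region_mode!r}")
        d_rho, d_w = REGION_DEFAULTS[self.region_mode]
        if self.rho is None:
            self.rho = d_rho
        if self.window is None:
            self.window = d_w
        if self.rho < 2:
            raise ConfigError(f"rho must be >= 2, got {self.rho}")
        if self.window < 1:
            raise ConfigError(f"window must be >= 1, got {self.window}")


@dataclass
class LabeledDataset:
    """Ordered variants with ±1 labels and their fold key (chromosome).

    ``excluded`` holds the intermediate-recurrence variants (1 < r < rho)
    set aside during labeling; they never enter training but are needed to
    relabel at other thresholds.
    """

    variants: list[Variant]
    labels: np.ndarray  # +1 / -1, aligned to variants
    config: DatasetConfig
    excluded: list[Variant] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.variants) != len(self.labels):
            raise ValueError("variants and labels differ in length")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(
            [self.variants[i] for i in idx], self.labels[idx], self.config, self.excluded
        )


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def classify_region(variant: Variant, annotation) -> str:
    """"coding" iff the variant position overlaps any CDS interval."""
    hits = annotation.overlapping(variant.chrom, variant.pos, "CDS")
    return "coding" if hits else "noncoding"


def classify_regions(variants: Iterable[Variant], annotation) -> list[Variant]:
    """Return copies of `variants` with their region field filled in."""
    out = []
    seen_missing: set[str] = set()
    annotated_chroms = {iv.chrom for iv in annotation.intervals if iv.kind == "CDS"}
    for v in variants:
        if v.chrom not in annotated_chroms and v.chrom not in seen_missing:
            seen_missing.add(v.chrom)
            warnings.warn(f"no CDS intervals on {v.chrom}; treating it as non-coding")
        out.append(replace(v, region=classify_region(v, annotation)))
    return out


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def assign_labels(
    variants: Sequence[Variant], cfg: DatasetConfig
) -> tuple[list[Variant], list[Variant], list[Variant]]:
    """Partition by recurrence: positives (r >= rho), negatives (r == 1),
    excluded (1 < r < rho)."""
    if cfg.rho < 2:
        raise ConfigError(f"rho must be >= 2, got {cfg.rho}")
    positives = [v for v in variants if v.r >= cfg.rho]
    negatives = [v for v in variants if v.r == 1]
    excluded = [v for v in variants if 1 < v.r < cfg.rho]
    return positives, negatives, excluded


def window_match(
    negatives: Sequence[Variant], positives: Sequence[Variant], w: int
) -> list[Variant]:
    """Negatives within |Δpos| <= w of any positive on the same chromosome.

    Boundary-inclusive; order of `negatives` is preserved.  Uses sorted
    positive positions per chromosome, O((N+M) log M).
    """
    if w < 1:
        raise ConfigError(f"window must be >= 1, got {w}")
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in positives}:
        pos_by_chrom[chrom] = np.sort(
            np.array([p.pos for p in positives if p.chrom == chrom])
        )
    kept = []
    for v in negatives:
        arr = pos_by_chrom.get(v.chrom)
        if arr is None:
            continue
        i = int(np.searchsorted(arr, v.pos))
        near = (i < len(arr) and arr[i] - v.pos <= w) or (
            i > 0 and v.pos - arr[i - 1] <= w
        )
        if near:
            kept.append(v)
    return kept


def build_dataset(variants: Sequence[Variant], cfg: DatasetConfig) -> LabeledDataset:
    """Label, window-match and assemble a dataset for one region mode.

    Variants whose region field is assigned are filtered to
    ``cfg.region_mode``; unassigned variants are taken as-is.  The pool is
    canonically ordered by (chrom, pos, alt) so the result does not depend
    on catalog order.
    """
    pool = [v for v in variants if v.region in (cfg.region_mode, "unassigned")]
    pool.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    positives, negatives, excluded = assign_labels(pool, cfg)
    matched = window_match(negatives, positives, cfg.window)
    ordered = positives + matched
    labels = np.concatenate([np.ones(len(positives), int), -np.ones(len(matched), int)])
    return LabeledDataset(ordered, labels, cfg, excluded=excluded)


# ---------------------------------------------------------------------------
# Folds and subsampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    test_chrom: str
    train_chroms: tuple[str, ...]
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def degenerate(self) -> bool:
        return len(self.train_idx) == 0


def make_loco_folds(ds: LabeledDataset) -> list[Fold]:
    """One leave-one-chromosome-out fold per autosome present in the data.

    Examples on X, Y and MT never appear in any fold, on either side.
    """
    chroms = ds.chroms
    autosomal = np.isin(chroms, AUTOSOMES)
    present = [c for c in AUTOSOMES if (chroms == c).any()]
    if not present:
        raise DegenerateDataError("dataset has no autosomal examples")
    folds = []
    for test_chrom in present:
        test_mask = chroms == test_chrom
        train_mask = autosomal & ~test_mask
        fold = Fold(
            test_chrom=test_chrom,
            train_chroms=tuple(c for c in present if c != test_chrom),
            train_idx=np.nonzero(train_mask)[0],
            test_idx=np.nonzero(test_mask)[0],
        )
        if fold.degenerate:
            warnings.warn(f"fold {test_chrom}: empty training set (single-autosome data)")
        folds.append(fold)
    return folds


def balanced_subsample(
    ds: LabeledDataset, n_per_class: int, seed: int
) -> LabeledDataset:
    """Uniform without-replacement subsample of min(n_per_class, class size)
    per class, with its own seeded generator."""
    idx = balanced_subsample_idx(ds.labels, n_per_class, seed)
    return ds.subset(idx)


def balanced_subsample_idx(
    labels: np.ndarray, n_per_class: int, seed: int
) -> np.ndarray:
    labels = np.asarray(labels)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == -1)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDataError("both classes must be non-empty for subsampling")
    if n_per_class > max(len(pos), len(neg)):
        warnings.warn(
            f"n_per_class={n_per_class} exceeds both class sizes "
            f"({len(pos)} positive, {len(neg)} negative); returning all examples"
        )
    rng = np.random.default_rng(seed)
    take_pos = rng.choice(pos, size=min(n_per_class, len(pos)), replace=False)
    take_neg = rng.choice(neg, size=min(n_per_class, len(neg)), replace=False)
    return np.sort(np.concatenate([take_pos, take_neg]))
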