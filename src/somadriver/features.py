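"""Per-variant genomic feature groups.

Seven groups are computed from the reference sequence, the somatic catalog,
the gene annotation, per-position score tracks and functional-element
intervals:

* ``Conservation`` — values of conservation-type tracks (PhastCons/PhyloP
  style) at the variant position.
* ``Uniqueness`` — values of sequence-uniqueness-type tracks.
* ``GC`` — G+C fraction of a window centred on the variant.
* ``LocalMutFreq`` — number of other catalog variants within a fixed-width
  window (mutation density).
* ``GeneProximity`` — distance to the nearest annotated gene feature of
  each configured kind (log1p-transformed by default).
* ``Spectrum`` — normalized k-mer frequency vector of the window.
* ``FunctionalElements`` — binary overlap indicators per element class.

Missing values use the NaN sentinel from :mod:`somadriver.io_formats` and
are imputed at assembly time from training rows only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import ConfigError, Variant
from .io_formats import MISSING, GenomeSequence, IntervalSet, ScoreTrack

GROUP_NAMES = (
    "Conservation",
    "GC",
    "Uniqueness",
    "LocalMutFreq",
    "GeneProximity",
    "Spectrum",
    "FunctionalElements",
)


@dataclass
class FeatureConfig:
    gc_window: int = 100
    spectrum_k: int = 3
    spectrum_window: int = 100
    mutfreq_window: int = 1000
    proximity_kinds: tuple[str, ...] = ("TSS", "splice_site", "TFBS")
    log_distance: bool = True
    element_classes: tuple[str, ...] = ("enhancer_like", "promoter_like")
    impute_policy: str = "train_mean"

    def __post_init__(self):
        if self.gc_window < 1 or self.mutfreq_window < 1 or self.spectrum_window < 1:
            raise ConfigError("windows must be >= 1")
        if not 1 <= self.spectrum_k <= 5:
            raise ConfigError(f"spectrum_k must be in [1, 5], got {self.spectrum_k}")
        if self.spectrum_window < self.spectrum_k:
            raise ConfigError("spectrum window must be >= k")
        if self.impute_policy not in {"train_mean", "zero"}:
            raise ConfigError(f"unknown impute_policy {self.impute_policy!r}")


@dataclass
class FeatureGroupMatrix:
    """One feature group's matrix, row-aligned to a dataset."""

    group_name: str
    X: np.ndarray  # floats, NaN = missing
    columns: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("matrix shape does not match column labels")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.X)


# ---------------------------------------------------------------------------
# Scalar extractors
# ---------------------------------------------------------------------------

def _centered_window(pos1: int, width: int) -> tuple[int, int]:
    """0-based half-open window of `width` bases centred on a 1-based pos."""
    start0 = pos1 - 1 - (width - 1) // 2
    return start0, start0 + width


def gc_content(genome: GenomeSequence, variant: Variant, window: int) -> float:
    """G+C fraction among non-N bases of the centred window (end-clipped)."""
    if window < 1:
        raise ConfigError(f"window must be >= 1, got {window}")
    length = genome.lengths.get(variant.chrom)
    if length is None or not 1 <= variant.pos <= length:
        raise ValueError(f"{variant.chrom}:{variant.pos} outside the genome")
    s, e = _centered_window(variant.pos, window)
    seq = genome.window_clipped(variant.chrom, s, e)
    valid = [b for b in seq if b != "N"]
    if not valid:
        return MISSING
    return sum(b in "GC" for b in valid) / len(valid)


def local_mutation_frequency(
    variant: Variant, catalog: Sequence[Variant], window: int
) -> int:
    """Count of other catalog variants within |Δpos| <= window/2 on the
    variant's chromosome.  The query variant itself (same chrom, pos, alt)
    is excluded; a distinct variant at the same position counts."""
    half = window / 2
    n = 0
    for c in catalog:
        if c.chrom == variant.chrom and abs(c.pos - variant.pos) <= half:
            if (c.pos, c.ref, c.alt) != (variant.pos, variant.ref, variant.alt):
                n += 1
    return n


def _kmer_index(k: int) -> dict[str, int]:
    return {"".join(t): i for i, t in enumerate(itertools.product("ACGT", repeat=k))}


def spectrum(
    genome: GenomeSequence, variant: Variant, k: int, window: int
) -> np.ndarray:
    """Normalized k-mer frequency vector (length 4^k) of the centred window.

    k-mers containing N are skipped; with no valid k-mer the whole vector is
    missing."""
    if window < k:
        raise ConfigError(f"spectrum window {window} < k {k}")
    s, e = _centered_window(variant.pos, window)
    seq = genome.window_clipped(variant.chrom, s, e)
    index = _kmer_index(k)
    counts = np.zeros(4 ** k)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" not in kmer:
            counts[index[kmer]] += 1
    total = counts.sum()
    if total == 0:
        return np.full(4 ** k, MISSING)
    return counts / total


def proximity_features(
    variant: Variant,
    annotation: IntervalSet,
    kinds: Sequence[str],
    log_distance: bool = True,
) -> np.ndarray:
    """Distance to the nearest interval of each kind (0 when overlapping;
    missing when the chromosome has none of that kind)."""
    from .io_formats import FEATURE_KINDS

    unknown = set(kinds) - FEATURE_KINDS
    if unknown:
        raise ConfigError(f"unknown feature kinds {sorted(unknown)}")
    out = np.empty(len(kinds))
    for j, kind in enumerate(kinds):
        d = annotation.nearest_distance(variant.chrom, variant.pos, kind)
        out[j] = math.log1p(d) if (log_distance and not math.isnan(d)) else d
    return out


def track_features(
    variant: Variant, tracks: Mapping[str, ScoreTrack]
) -> np.ndarray:
    """Per-track score at the variant position; missing where absent."""
    return np.array(
        [tracks[name].value_at(variant.chrom, variant.pos) for name in tracks]
    )


def functional_element_features(
    variant: Variant, elements: IntervalSet, element_classes: Sequence[str]
) -> np.ndarray:
    """One 0/1 indicator per element class for overlap at the position."""
    hits = elements.overlapping(variant.chrom, variant.pos, "functional_element")
    present = {iv.label for iv in hits}
    return np.array([1.0 if c in present else 0.0 for c in element_classes])


# ---------------------------------------------------------------------------
# Group assembly
# ---------------------------------------------------------------------------

def compute_feature_groups(
    variants: Sequence[Variant],
    genome: GenomeSequence,
    annotation: IntervalSet,
    conservation_tracks: Mapping[str, ScoreTrack],
    uniqueness_tracks: Mapping[str, ScoreTrack],
    elements: IntervalSet,
    catalog: Sequence[Variant],
    cfg: FeatureConfig | None = None,
) -> dict[str, FeatureGroupMatrix]:
    """Compute all seven groups, row-aligned to `variants`.

    `catalog` is the full somatic catalog (all recurrence levels) used for
    mutation density; it normally contains `variants` and more.
    """
    cfg = cfg or FeatureConfig()
    n = len(variants)

    cons = np.array([track_features(v, conservation_tracks) for v in variants]).reshape(n, -1)
    uniq = np.array([track_features(v, uniqueness_tracks) for v in variants]).reshape(n, -1)
    gc = np.array([[gc_content(genome, v, cfg.gc_window)] for v in variants])
    mutfreq = _mutfreq_matrix(variants, catalog, cfg.mutfreq_window)
    prox = np.array(
        [proximity_features(v, annotation, cfg.proximity_kinds, cfg.log_distance)
         for v in variants]
    ).reshape(n, len(cfg.proximity_kinds))
    spec = np.array(
        [spectrum(genome, v, cfg.spectrum_k, cfg.spectrum_window) for v in variants]
    ).reshape(n, 4 ** cfg.spectrum_k)
    func = np.array(
        [functional_element_features(v, elements, cfg.element_classes) for v in variants]
    ).reshape(n, len(cfg.element_classes))

    kmers = ["".join(t) for t in itertools.product("ACGT", repeat=cfg.spectrum_k)]
    return {
        "Conservation": FeatureGroupMatrix("Conservation", cons, list(conservation_tracks)),
        "GC": FeatureGroupMatrix("GC", gc, [f"gc_{cfg.gc_window}"]),
        "Uniqueness": FeatureGroupMatrix("Uniqueness", uniq, list(uniqueness_tracks)),
        "LocalMutFreq": FeatureGroupMatrix(
            "LocalMutFreq", mutfreq, [f"mutfreq_{cfg.mutfreq_window}"]
        ),
        "GeneProximity": FeatureGroupMatrix(
            "GeneProximity", prox, [f"dist_{k}" for k in cfg.proximity_kinds]
        ),
        "Spectrum": FeatureGroupMatrix("Spectrum", spec, kmers),
        "FunctionalElements": FeatureGroupMatrix(
            "FunctionalElements", func, list(cfg.element_classes)
        ),
    }


def _mutfreq_matrix(
    variants: Sequence[Variant], catalog: Sequence[Variant], window: int
) -> np.ndarray:
    """Vectorized mutation-density counts via sorted catalog positions."""
    half = window / 2
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {c.chrom for c in catalog}:
        by_chrom[chrom] = np.sort(np.array([c.pos for c in catalog if c.chrom == chrom]))
    self_keys = {}
    for c in catalog:
        self_keys.setdefault((c.chrom, c.pos), []).append((c.ref, c.alt))
    out = np.zeros((len(variants), 1))
    for i, v in enumerate(variants):
        arr = by_chrom.get(v.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, v.pos - half, side="left")
        hi = np.searchsorted(arr, v.pos + half, side="right")
        n = int(hi - lo)
        # subtract the query variant itself if present in the catalog
        n -= sum(1 for ra in self_keys.get((v.chrom, v.pos), []) if ra == (v.ref, v.alt))
        out[i, 0] = n
    return out


def assemble(
    groups: Mapping[str, FeatureGroupMatrix],
    selected: Sequence[str],
    train_rows: np.ndarray | None = None,
    impute_policy: str = "train_mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Column-concatenate the selected groups and impute missing cells.

    Imputation statistics come from ``train_rows`` only (all rows when
    None).  A column that is missing in every training row is imputed with
    0.  Returns the finite matrix and the imputation values per column.
    """
    mats = []
    n_rows = None
    for name in selected:
        if name not in groups:
            raise KeyError(f"unknown feature group {name!r}")
        g = groups[name]
        if n_rows is None:
            n_rows = g.n_rows
        elif g.n_rows != n_rows:
            raise ValueError(
                f"group {name!r} has {g.n_rows} rows, expected {n_rows}"
            )
        mats.append(g.X)
    X = np.concatenate(mats, axis=1).astype(float)
    if train_rows is None:
        train_rows = np.arange(X.shape[0])
    if impute_policy == "zero":
        fill = np.zeros(X.shape[1])
    else:
        with np.errstate(invalid="ignore"):
            fill = np.nanmean(X[train_rows], axis=0)
        fill = np.where(np.isnan(fill), 0.0, fill)
    X = np.where(np.isnan(X), fill[None, :], X)
    return X, fill
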