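"""Readers and writers for the genomic file formats the pipeline touches.

All coordinate dialects are reconciled at this boundary: internally every
interval is 0-based half-open and every variant position is 1-based (as in
VCF).  Nothing outside this module parses or emits a file format.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .dataset import Variant

#: Sentinel for "no value at this position".  NaN (not a magic number like -1)
#: so that negative-valued tracks such as PhyloP are representable.
MISSING: float = math.nan

FEATURE_KINDS = frozenset({"CDS", "splice_site", "TSS", "TFBS", "functional_element"})

_NUCS = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class CoordinateError(ValueError):
    """Raised when a query falls outside a chromosome."""


# ---------------------------------------------------------------------------
# GenomeSequence
# ---------------------------------------------------------------------------

class GenomeSequence:
    """In-memory reference genome over the alphabet {A, C, G, T, N}.

    Window queries are strict: asking for bases outside ``[1, length]``
    raises :class:`CoordinateError` rather than silently truncating.  Callers
    that want end-clipped windows (e.g. GC content near a telomere) use
    :meth:`window_clipped`.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {normalize_chrom(c): s.upper() for c, s in sequences.items()}
        self.lengths = {c: len(s) for c, s in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        with Fasta(str(path), as_raw=True, rebuild=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, chrom: str) -> str:
        chrom = normalize_chrom(chrom)
        if chrom not in self._seqs:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        return self._seqs[chrom]

    def window(self, chrom: str, start0: int, end0: int) -> str:
        """Bases in the 0-based half-open window ``[start0, end0)``."""
        seq = self.sequence(chrom)
        if start0 < 0 or end0 > len(seq) or start0 > end0:
            raise CoordinateError(
                f"window [{start0}, {end0}) outside {chrom} (length {len(seq)})"
            )
        return seq[start0:end0]

    def window_clipped(self, chrom: str, start0: int, end0: int) -> str:
        """Like :meth:`window` but clipped to the chromosome ends."""
        seq = self.sequence(chrom)
        return seq[max(0, start0):min(len(seq), end0)]

    def base(self, chrom: str, pos1: int) -> str:
        """Reference base at a 1-based position."""
        return self.window(chrom, pos1 - 1, pos1)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# ScoreTrack
# ---------------------------------------------------------------------------

class ScoreTrack:
    """Sparse per-position score track with run-length interval storage.

    Positions are 1-based at the query interface.  Queries outside any stored
    interval return :data:`MISSING`.
    """

    def __init__(self) -> None:
        # chrom -> (starts0, ends0, values), sorted by start, non-overlapping
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int, float]]
    ) -> "ScoreTrack":
        """Build from 0-based half-open (chrom, start, end, value) rows.

        Later rows win on overlap (with a warning), matching bedGraph
        last-line-wins semantics.
        """
        track = cls()
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            chrom = normalize_chrom(chrom)
            if start < 0 or end < start:
                raise FormatError(f"bad interval [{start}, {end}) on {chrom}")
            if not math.isfinite(value):
                raise FormatError(f"non-finite score {value} on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, runs in by_chrom.items():
            track._runs[chrom] = _flatten_runs(chrom, runs)
        return track

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def value_at(self, chrom: str, pos1: int) -> float:
        """Score at a 1-based position, or :data:`MISSING`."""
        if pos1 < 1:
            raise CoordinateError(f"position {pos1} is not positive")
        chrom = normalize_chrom(chrom)
        runs = self._runs.get(chrom)
        if runs is None:
            return MISSING
        starts, ends, values = runs
        p0 = pos1 - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        if i >= 0 and p0 < ends[i]:
            return float(values[i])
        return MISSING

    def values_at(self, chrom: str, positions1: Sequence[int]) -> np.ndarray:
        return np.array([self.value_at(chrom, int(p)) for p in positions1])

    def iter_runs(self):
        for chrom, (starts, ends, values) in self._runs.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


def _flatten_runs(
    chrom: str, runs: list[tuple[int, int, float]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve overlaps last-wins and return sorted disjoint runs."""
    # Sweep boundaries; later list index takes precedence.
    bounds = sorted({b for s, e, _ in runs for b in (s, e)})
    if not bounds:
        empty = np.array([])
        return empty, empty, empty
    starts_in = np.array([s for s, _, _ in runs])
    ends_in = np.array([e for _, e, _ in runs])
    out_s: list[int] = []
    out_e: list[int] = []
    out_v: list[float] = []
    overlapped = False
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        covering = np.nonzero((starts_in <= lo) & (ends_in >= hi))[0]
        if covering.size == 0:
            continue
        if covering.size > 1:
            overlapped = True
        v = runs[int(covering[-1])][2]  # last line wins
        if out_s and out_e[-1] == lo and out_v[-1] == v:
            out_e[-1] = hi
        else:
            out_s.append(lo)
            out_e.append(hi)
            out_v.append(v)
    if overlapped:
        warnings.warn(f"overlapping bedGraph intervals on {chrom}; last line wins")
    return np.array(out_s), np.array(out_e), np.array(out_v)


def read_track(path: str | Path) -> ScoreTrack:
    """Read a 4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return ScoreTrack.from_intervals(rows)


def write_track(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.iter_runs():
            fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")  # shortest exact float repr


# ---------------------------------------------------------------------------
# IntervalSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """One typed interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    kind: str
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(f"start {self.start} > end {self.end}")


class IntervalSet:
    """Typed genomic intervals with overlap and nearest-neighbour queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals: list[GenomicInterval] = []
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        if iv.kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {iv.kind!r}")
        iv = GenomicInterval(
            normalize_chrom(iv.chrom), iv.start, iv.end, iv.kind, iv.strand, iv.label
        )
        self.intervals.append(iv)
        key = (iv.chrom, iv.kind)
        tree = self._trees.setdefault(key, IntervalTree())
        if iv.start < iv.end:  # intervaltree rejects empty intervals
            tree.addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def of_kind(self, kind: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.kind == kind]

    def overlapping(self, chrom: str, pos1: int, kind: str) -> list[GenomicInterval]:
        """Intervals of `kind` overlapping a 1-based position."""
        tree = self._trees.get((normalize_chrom(chrom), kind))
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos1 - 1)]

    def nearest_distance(self, chrom: str, pos1: int, kind: str) -> float:
        """Nucleotide distance from a 1-based position to the nearest
        interval of `kind` on the same chromosome (0 when overlapping);
        :data:`MISSING` when the chromosome carries none."""
        chrom = normalize_chrom(chrom)
        candidates = [
            iv for iv in self.intervals if iv.chrom == chrom and iv.kind == kind
        ]
        if not candidates:
            return MISSING
        p0 = pos1 - 1
        best = math.inf
        for iv in candidates:
            if iv.start <= p0 < iv.end:
                return 0.0
            # distance to closed set [start, end-1] (end may equal start)
            if iv.start == iv.end:
                d = abs(p0 - iv.start)
            else:
                d = max(iv.start - p0, p0 - (iv.end - 1), 0)
            best = min(best, d)
        return float(best)


def read_intervals(
    path: str | Path,
    fmt: str,
    kind_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> tuple[IntervalSet, int]:
    """Read BED (0-based half-open) or GFF3 (1-based closed) intervals.

    `kind_map` translates the file's feature names (BED column 4 / GFF3
    column 3) into the internal vocabulary.  Returns the set and the number
    of records dropped for unmappable kinds (strict=False only).
    """
    if fmt not in {"bed", "gff3"}:
        raise ValueError(f"fmt must be 'bed' or 'gff3', got {fmt!r}")
    kind_map = dict(kind_map or {k: k for k in FEATURE_KINDS})
    out = IntervalSet()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "bed":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    raw_kind = parts[3] if len(parts) > 3 else ""
                    strand = parts[5] if len(parts) > 5 else "."
                    label = parts[4] if len(parts) > 4 else ""
                else:
                    chrom, raw_kind = parts[0], parts[2]
                    start, end = int(parts[3]) - 1, int(parts[4])  # to 0-based half-open
                    strand = parts[6] if len(parts) > 6 else "."
                    label = parts[8] if len(parts) > 8 else ""
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if raw_kind not in kind_map:
                if strict:
                    raise FormatError(f"{path}:{lineno}: unknown feature kind {raw_kind!r}")
                dropped += 1
                continue
            out.add(GenomicInterval(chrom, start, end, kind_map[raw_kind], strand, label))
    return out, dropped


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.kind}\t{iv.label}\t{iv.strand}\n")


def write_gff3(intervals: IntervalSet, path: str | Path, source: str = "somadriver") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals.intervals:
            fh.write(
                f"{iv.chrom}\t{source}\t{iv.kind}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{iv.label or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------

@dataclass
class SkipReport:
    """Accounting of records dropped by :func:`read_variants`.

    ``raw + extra_alts`` candidate alleles = retained + skipped (multi-allelic
    records contribute one candidate per ALT)."""

    raw: int = 0
    extra_alts: int = 0
    non_snv: int = 0
    missing_recurrence: int = 0

    @property
    def skipped(self) -> int:
        return self.non_snv + self.missing_recurrence


def read_variants(
    path: str | Path,
    recurrence_key: str = "CNT",
    default_recurrence: int | None = None,
) -> tuple[list[Variant], SkipReport]:
    """Read somatic SNVs from a VCF 4.x file.

    Multi-allelic records are split into one candidate per ALT; non-SNV
    alleles are skipped and counted.  Recurrence is parsed from the INFO
    field ``recurrence_key``; records lacking it take ``default_recurrence``
    or, when that is None, raise :class:`FormatError`.
    """
    report = SkipReport()
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            report.raw += 1
            alts = rec.alts or ()
            report.extra_alts += max(0, len(alts) - 1)
            r = rec.info.get(recurrence_key)
            if isinstance(r, tuple):
                r = r[0]
            for alt in alts:
                if (
                    alt is None
                    or len(rec.ref) != 1
                    or len(alt) != 1
                    or rec.ref.upper() not in _NUCS
                    or alt.upper() not in _NUCS
                    or rec.ref.upper() == alt.upper()
                ):
                    report.non_snv += 1
                    continue
                if r is None:
                    if default_recurrence is None:
                        raise FormatError(
                            f"record {rec.chrom}:{rec.pos} lacks INFO/{recurrence_key} "
                            "and no default recurrence is configured"
                        )
                    r_use = default_recurrence
                else:
                    r_use = int(r)
                variants.append(
                    Variant(
                        chrom=normalize_chrom(rec.chrom),
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        r=r_use,
                    )
                )
    return variants, report


def write_variants_vcf(
    variants: Sequence[Variant],
    path: str | Path,
    contig_lengths: Mapping[str, int],
    recurrence_key: str = "CNT",
) -> None:
    """Write SNVs to an uncompressed VCF 4.2 file with recurrence in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            f'##INFO=<ID={recurrence_key},Number=1,Type=Integer,'
            'Description="Recurrence count across samples">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{recurrence_key}={v.r}\n"
            )


# ---------------------------------------------------------------------------
# Predictions (TSV)
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ("chrom", "pos", "ref", "alt", "score", "label", "high_confidence")


def write_predictions(
    records: Iterable[tuple[Variant, float, str, bool]],
    path: str | Path,
    decimals: int = 4,
) -> None:
    """Write scored variants as TSV, ordered by (chrom, pos, alt).

    ``label`` is "+" for scores at or above 0.5 and "-" below.
    """
    rows = sorted(records, key=lambda r: (r[0].chrom, r[0].pos, r[0].alt))
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for v, score, label, confident in rows:
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"score {score} outside [0, 1]")
            if label not in {"+", "-"}:
                raise ValueError(f"label must be '+' or '-', got {label!r}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{score:.{decimals}f}\t{label}\t{int(confident)}\n"
            )


def read_predictions(path: str | Path):
    """Read a predictions TSV back into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype={"label": str})


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def normalize_chrom(name: str) -> str:
    """Normalize chromosome aliases: "1" and "chr1" both become "chr1"."""
    name = str(name).strip()
    if name.upper().startswith("CHR"):
        body = name[3:]
    else:
        body = name
    body = {"M": "MT", "m": "MT"}.get(body, body)
    return "chr" + body.upper() if body.upper() in {"X", "Y", "MT"} else "chr" + body
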