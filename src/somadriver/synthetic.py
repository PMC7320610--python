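"""Seeded synthetic genomes, annotations, score tracks and somatic catalogs.

The generator emulates the structure the classifier assumes: a small set of
mutation hotspots carries highly recurrent ("driver-like") SNVs, while
singleton ("passenger-like") SNVs are scattered both near hotspots (so that
window matching retains them) and far away (so that it filters something).
Class-conditional feature differences are planted with configurable effect
sizes, expressed in SD units of the baseline feature distribution:

* Conservation / Uniqueness — per-position score-track values at driver
  positions are drawn from the baseline distribution shifted by the effect.
* GC / Spectrum — the reference sequence around driver positions is
  rewritten with shifted G+C probability (GC) or nucleotide autocorrelation
  (Spectrum).
* LocalMutFreq — extra intermediate-recurrence (r=2) "clutter" variants are
  planted around driver positions; they inflate local mutation density but
  are excluded from training by the labeling rule.
* GeneProximity — a fraction of drivers is relocated next to a TSS.
* FunctionalElements — functional elements are planted over a fraction of
  drivers.

With all effects at zero, drivers and near-hotspot passengers are drawn
from the same spatial law and no overrides occur, so every feature is
identically distributed across classes (an exact null).

An optional germline-like cohort (uniformly placed, with its own track
shifts) supports class-conditional distribution comparisons of the
germline-versus-rare-somatic kind.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import Variant
from .io_formats import (
    GenomeSequence,
    GenomicInterval,
    IntervalSet,
    ScoreTrack,
    write_bed,
    write_fasta,
    write_gff3,
    write_track,
    write_variants_vcf,
)

_NUCS = np.array(list("ACGT"))

#: Baseline track distributions: (mean, sd, clip to [0,1]?)
TRACK_SPECS = {
    "phastcons_like": (0.5, 0.15, True),
    "phylop_like": (0.0, 1.0, False),
    "uniqueness_like": (0.5, 0.15, True),
}
CONSERVATION_TRACKS = ("phastcons_like", "phylop_like")
UNIQUENESS_TRACKS = ("uniqueness_like",)


def default_effect_sizes() -> dict[str, float]:
    """Default planted driver-vs-passenger shifts (SD units).

    Conservation and mutation density shift the most, matching the pattern
    that recurrent somatic variants concentrate in constrained, mutation-
    dense regions; sequence-composition and annotation effects are milder.
    """
    return {
        "Conservation": 1.0,
        "Uniqueness": 0.75,
        "LocalMutFreq": 0.75,
        "GC": 0.5,
        "GeneProximity": 0.5,
        "Spectrum": 0.0,
        "FunctionalElements": 0.25,
    }


def default_germline_shifts() -> dict[str, float]:
    """Shift of the germline-like cohort relative to the somatic baseline:
    germline variants sit in less conserved, less unique sequence."""
    return {"Conservation": -1.0, "Uniqueness": -0.5}


@dataclass
class SimConfig:
    n_chroms: int = 4
    chrom_length: int = 200_000
    n_hotspots: int = 20
    n_drivers: int = 300
    n_passengers: int = 3000
    rho_sim: int = 8          # minimum driver recurrence
    r_max: int = 20
    r_geometric_p: float = 0.35
    near_fraction: float = 0.7
    cloud_radius: int = 800   # jitter of drivers and near passengers around a hotspot
    margin: int = 2000        # keep variants away from chromosome ends
    track_bin: int = 100
    effect_sizes: dict[str, float] = field(default_factory=default_effect_sizes)
    effect_vs_r: float = 0.0  # extra conservation shift per recurrence unit above 1
    germline_mode: bool = False
    n_germline: int = 3000
    germline_shifts: dict[str, float] = field(default_factory=default_germline_shifts)
    genes_per_chrom: int = 8
    tfbs_per_chrom: int = 10
    elements_per_chrom: int = 15
    element_width: int = 300
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chroms, self.chrom_length, self.n_hotspots,
               self.n_drivers, self.n_passengers) < 1:
            raise ValueError("counts and lengths must be positive")
        if not all(np.isfinite(v) for v in self.effect_sizes.values()):
            raise ValueError("effect sizes must be finite")
        if self.rho_sim < 2:
            raise ValueError("rho_sim must be >= 2")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeSequence
    annotation: IntervalSet
    elements: IntervalSet
    tracks: dict[str, ScoreTrack]
    somatic: list[Variant]          # full catalog incl. clutter
    germline: list[Variant]
    hotspots: list[tuple[str, int]]
    truth: dict                     # ground truth for test assertions

    @property
    def conservation_tracks(self) -> dict[str, ScoreTrack]:
        return {k: self.tracks[k] for k in CONSERVATION_TRACKS}

    @property
    def uniqueness_tracks(self) -> dict[str, ScoreTrack]:
        return {k: self.tracks[k] for k in UNIQUENESS_TRACKS}


# ---------------------------------------------------------------------------
# Orchestrated simulation
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full seeded simulation; byte-identical for a fixed config."""
    rng = np.random.default_rng(cfg.seed)
    e = {**default_effect_sizes(), **cfg.effect_sizes}

    annotation = _simulate_annotation(cfg, rng)
    tss_by_chrom = {
        c: [iv for iv in annotation.intervals if iv.kind == "TSS" and iv.chrom == c]
        for c in cfg.chrom_names
    }
    hotspots = _place_hotspots(cfg, rng)
    driver_pos, driver_r = _place_drivers(cfg, hotspots, tss_by_chrom, e, rng)
    passenger_pos = _place_passengers(cfg, hotspots, rng)
    clutter_pos = _place_clutter(cfg, driver_pos, e, rng)
    germline_pos = _place_germline(cfg, rng) if cfg.germline_mode else []

    genome = _simulate_sequence(cfg, driver_pos, e, rng)
    elements = _simulate_elements(cfg, driver_pos, e, rng)
    tracks = _simulate_tracks(
        cfg, driver_pos, driver_r, passenger_pos + clutter_pos, germline_pos, e, rng
    )

    def mkvar(chrom: str, pos: int, r: int) -> Variant:
        ref = genome.base(chrom, pos)
        alt = str(rng.choice([n for n in "ACGT" if n != ref]))
        return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, r=r)

    drivers = [mkvar(c, p, int(r)) for (c, p), r in zip(driver_pos, driver_r)]
    passengers = [mkvar(c, p, 1) for c, p in passenger_pos]
    clutter = [mkvar(c, p, 2) for c, p in clutter_pos]
    germline = [mkvar(c, p, 1) for c, p in germline_pos]

    truth = {
        "hotspots": [[c, int(p)] for c, p in hotspots],
        "drivers": [[v.chrom, v.pos, v.alt, v.r] for v in drivers],
        "n_passengers": len(passengers),
        "n_clutter": len(clutter),
        "effect_sizes": e,
        "effect_vs_r": cfg.effect_vs_r,
        "seed": cfg.seed,
    }
    return SimResult(
        config=cfg,
        genome=genome,
        annotation=annotation,
        elements=elements,
        tracks=tracks,
        somatic=drivers + passengers + clutter,
        germline=germline,
        hotspots=hotspots,
        truth=truth,
    )


def simulate_genome(cfg: SimConfig):
    """Genome-side artifacts of the simulation: (genome, annotation,
    tracks, elements).  A view over :func:`simulate` so that track
    elevations stay consistent with the catalog drawn under the same seed."""
    sim = simulate(cfg)
    return sim.genome, sim.annotation, sim.tracks, sim.elements


def simulate_catalog(cfg: SimConfig):
    """Catalog side of the simulation: (somatic variants, germline
    variants, truth).  A view over :func:`simulate` (same seed, same
    catalog)."""
    sim = simulate(cfg)
    return sim.somatic, sim.germline, sim.truth


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


def _place_hotspots(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    hotspots = []
    lo, hi = cfg.margin, cfg.chrom_length - cfg.margin
    for i in range(cfg.n_hotspots):
        chrom = cfg.chrom_names[i % cfg.n_chroms]
        hotspots.append((chrom, int(rng.integers(lo, hi))))
    return hotspots


def _jitter(cfg: SimConfig, rng: np.random.Generator) -> int:
    return int(rng.integers(-cfg.cloud_radius, cfg.cloud_radius + 1))


def _clip_pos(cfg: SimConfig, pos: int) -> int:
    return int(np.clip(pos, 1, cfg.chrom_length))


def _dedupe(used: set, chrom: str, pos: int, cfg: SimConfig) -> int:
    while (chrom, pos) in used:
        pos = _clip_pos(cfg, pos + 1)
    used.add((chrom, pos))
    return pos


def _place_drivers(cfg, hotspots, tss_by_chrom, e, rng):
    used: set = set()
    positions: list[tuple[str, int]] = []
    # truncated geometric recurrence on [rho_sim, r_max]
    raw = rng.geometric(cfg.r_geometric_p, size=cfg.n_drivers) - 1
    rs = np.minimum(cfg.rho_sim + raw, cfg.r_max)
    p_tss = min(0.8, 0.25 * e.get("GeneProximity", 0.0))
    for _ in range(cfg.n_drivers):
        chrom, center = hotspots[int(rng.integers(len(hotspots)))]
        pos = _clip_pos(cfg, center + _jitter(cfg, rng))
        if p_tss > 0 and tss_by_chrom[chrom] and rng.random() < p_tss:
            tss = tss_by_chrom[chrom][int(rng.integers(len(tss_by_chrom[chrom])))]
            pos = _clip_pos(cfg, tss.start + 1 + int(rng.integers(-200, 201)))
        positions.append((chrom, _dedupe(used, chrom, pos, cfg)))
    return positions, rs


def _place_passengers(cfg, hotspots, rng):
    used: set = set()
    n_near = int(round(cfg.near_fraction * cfg.n_passengers))
    out: list[tuple[str, int]] = []
    for _ in range(n_near):
        chrom, center = hotspots[int(rng.integers(len(hotspots)))]
        pos = _clip_pos(cfg, center + _jitter(cfg, rng))
        out.append((chrom, _dedupe(used, chrom, pos, cfg)))
    for _ in range(cfg.n_passengers - n_near):
        chrom = cfg.chrom_names[int(rng.integers(cfg.n_chroms))]
        pos = int(rng.integers(cfg.margin, cfg.chrom_length - cfg.margin))
        out.append((chrom, _dedupe(used, chrom, pos, cfg)))
    return out


def _place_clutter(cfg, driver_pos, e, rng):
    """Intermediate-recurrence variants planted around drivers to raise
    local mutation density by ~effect SD units."""
    eff = e.get("LocalMutFreq", 0.0)
    if eff <= 0:
        return []
    per_driver = eff * 4.0  # ~4 extra counts per SD unit at default densities
    used: set = set()
    out = []
    for chrom, pos in driver_pos:
        for _ in range(rng.poisson(per_driver)):
            p = _clip_pos(cfg, pos + int(rng.integers(-250, 251)))
            out.append((chrom, _dedupe(used, chrom, p, cfg)))
    return out


def _place_germline(cfg, rng):
    used: set = set()
    out = []
    for _ in range(cfg.n_germline):
        chrom = cfg.chrom_names[int(rng.integers(cfg.n_chroms))]
        pos = int(rng.integers(cfg.margin, cfg.chrom_length - cfg.margin))
        out.append((chrom, _dedupe(used, chrom, pos, cfg)))
    return out


# ---------------------------------------------------------------------------
# Sequence, annotation, elements, tracks
# ---------------------------------------------------------------------------


def _simulate_sequence(cfg, driver_pos, e, rng) -> GenomeSequence:
    seqs = {}
    for chrom in cfg.chrom_names:
        seqs[chrom] = rng.integers(0, 4, size=cfg.chrom_length)
    gc_eff = e.get("GC", 0.0)
    spec_eff = e.get("Spectrum", 0.0)
    if gc_eff or spec_eff:
        # GC fraction of a 100 bp window has SD ~ sqrt(0.25/100) = 0.05
        p_gc = float(np.clip(0.5 + 0.05 * gc_eff, 0.05, 0.95))
        p_repeat = float(np.clip(0.25 + 0.10 * spec_eff, 0.0, 0.9))
        for chrom, pos in driver_pos:
            arr = seqs[chrom]
            lo, hi = max(0, pos - 1 - 25), min(cfg.chrom_length, pos + 25)
            prev = None
            for i in range(lo, hi):
                if prev is not None and rng.random() < p_repeat:
                    arr[i] = prev
                elif rng.random() < p_gc:
                    arr[i] = rng.choice([1, 2])  # C or G
                else:
                    arr[i] = rng.choice([0, 3])  # A or T
                prev = arr[i]
    return GenomeSequence(
        {c: "".join(_NUCS[v] for v in seqs[c]) for c in cfg.chrom_names}
    )


def _simulate_annotation(cfg, rng) -> IntervalSet:
    out = IntervalSet()
    for chrom in cfg.chrom_names:
        for _ in range(cfg.genes_per_chrom):
            g = int(rng.integers(cfg.margin, cfg.chrom_length - cfg.margin - 3000))
            out.add(GenomicInterval(chrom, g, g + 1, "TSS", "+"))
            exon_start = g + 200
            for _ in range(3):  # three 300 bp CDS blocks, 500 bp apart
                out.add(GenomicInterval(chrom, exon_start, exon_start + 300, "CDS", "+"))
                for edge in (exon_start, exon_start + 300):
                    out.add(GenomicInterval(chrom, edge - 1, edge + 1, "splice_site", "+"))
                exon_start += 800
        for _ in range(cfg.tfbs_per_chrom):
            t = int(rng.integers(cfg.margin, cfg.chrom_length - cfg.margin))
            out.add(GenomicInterval(chrom, t, t + 10, "TFBS", "."))
    return out


def _simulate_elements(cfg, driver_pos, e, rng) -> IntervalSet:
    out = IntervalSet()
    classes = ("enhancer_like", "promoter_like")
    for chrom in cfg.chrom_names:
        for _ in range(cfg.elements_per_chrom):
            s = int(rng.integers(0, cfg.chrom_length - cfg.element_width))
            out.add(GenomicInterval(
                chrom, s, s + cfg.element_width, "functional_element", ".",
                label=str(rng.choice(classes)),
            ))
    p_overlap = min(0.9, 0.3 * e.get("FunctionalElements", 0.0))
    if p_overlap > 0:
        for chrom, pos in driver_pos:
            if rng.random() < p_overlap:
                s = max(0, pos - 1 - int(rng.integers(0, cfg.element_width)))
                out.add(GenomicInterval(
                    chrom, s, s + cfg.element_width, "functional_element", ".",
                    label=str(rng.choice(classes)),
                ))
    return out


def _simulate_tracks(cfg, driver_pos, driver_r, other_pos, germline_pos, e, rng):
    """Baseline per-bin tracks with per-position overrides at driver (and,
    in germline mode, germline) positions implementing the planted shifts."""
    shifts_by_track: dict[str, dict[tuple[str, int], float]] = {
        name: {} for name in TRACK_SPECS
    }
    e_cons = e.get("Conservation", 0.0)
    e_uniq = e.get("Uniqueness", 0.0)
    g_cons = cfg.germline_shifts.get("Conservation", 0.0)
    g_uniq = cfg.germline_shifts.get("Uniqueness", 0.0)
    if cfg.germline_mode:
        for chrom, pos in germline_pos:
            for name in CONSERVATION_TRACKS:
                shifts_by_track[name][(chrom, pos)] = g_cons
            for name in UNIQUENESS_TRACKS:
                shifts_by_track[name][(chrom, pos)] = g_uniq
    for (chrom, pos), r in zip(driver_pos, driver_r):
        extra = cfg.effect_vs_r * (int(r) - 1)
        for name in CONSERVATION_TRACKS:
            shifts_by_track[name][(chrom, pos)] = e_cons + extra
        for name in UNIQUENESS_TRACKS:
            shifts_by_track[name][(chrom, pos)] = e_uniq

    tracks = {}
    for name, (mu, sd, clip) in TRACK_SPECS.items():
        rows: list[tuple[str, int, int, float]] = []
        shifts = shifts_by_track[name]
        for chrom in cfg.chrom_names:
            n_bins = -(-cfg.chrom_length // cfg.track_bin)
            values = rng.normal(mu, sd, size=n_bins)
            overrides = {
                pos: rng.normal(mu + s * sd, sd)
                for (c, pos), s in shifts.items() if c == chrom
            }
            if clip:
                values = np.clip(values, 0.0, 1.0)
                overrides = {p: float(np.clip(v, 0.0, 1.0)) for p, v in overrides.items()}
            rows.extend(_bins_with_overrides(chrom, cfg, values, overrides))
        tracks[name] = ScoreTrack.from_intervals(rows)
    return tracks


def _bins_with_overrides(chrom, cfg, bin_values, overrides):
    """Disjoint bedGraph-style rows: baseline bins cut around override
    positions (1-based) so the assembled rows never overlap."""
    cut_points = sorted(overrides)
    rows = []
    ci = 0
    for b, value in enumerate(bin_values):
        s = b * cfg.track_bin
        end = min((b + 1) * cfg.track_bin, cfg.chrom_length)
        cur = s
        while ci < len(cut_points) and cut_points[ci] - 1 < end:
            p0 = cut_points[ci] - 1
            if cur < p0:
                rows.append((chrom, cur, p0, float(value)))
            rows.append((chrom, p0, p0 + 1, overrides[cut_points[ci]]))
            cur = p0 + 1
            ci += 1
        if cur < end:
            rows.append((chrom, cur, end, float(value)))
    return rows


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------


def write_fixture(sim: SimResult, outdir: str | Path) -> dict:
    """Write the simulation as plain-text files and a ground-truth manifest.

    Emits ref.fa, genes.gff3, elements.bed, tracks/*.bedgraph, somatic.vcf,
    optional germline.vcf and manifest.json; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    write_fasta(sim.genome, outdir / "ref.fa")
    write_gff3(sim.annotation, outdir / "genes.gff3")
    write_bed(sim.elements, outdir / "elements.bed")
    for name, track in sim.tracks.items():
        write_track(track, outdir / "tracks" / f"{name}.bedgraph")
    lengths = sim.genome.lengths
    write_variants_vcf(sim.somatic, outdir / "somatic.vcf", lengths)
    if sim.germline:
        write_variants_vcf(sim.germline, outdir / "germline.vcf", lengths)
    manifest = {
        "config": _config_dict(sim.config),
        "truth": sim.truth,
        "files": {
            "genome": "ref.fa",
            "annotation": "genes.gff3",
            "elements": "elements.bed",
            "tracks": {n: f"tracks/{n}.bedgraph" for n in sim.tracks},
            "somatic": "somatic.vcf",
            "germline": "germline.vcf" if sim.germline else None,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _config_dict(cfg: SimConfig) -> dict:
    return dataclasses.asdict(cfg)
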