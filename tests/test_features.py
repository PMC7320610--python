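"""Feature extractors against brute-force oracles, plus assembly/imputation."""

import itertools
import math

import numpy as np
import pytest

import somadriver.features as feat
from somadriver.dataset import Variant
from somadriver.io_formats import GenomeSequence, GenomicInterval, IntervalSet, ScoreTrack


def V(chrom="chr1", pos=50, ref="A", alt="G", r=1):
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, r=r)


def random_genome(rng, length=2000):
    return GenomeSequence({"chr1": "".join(rng.choice(list("ACGT"), length))})


# ---------------------------------------------------------------------------
# gc_content
# ---------------------------------------------------------------------------

def test_gc_content_extremes():
    g = GenomeSequence({"chr1": "GGCCATAT"})
    assert feat.gc_content(g, V(pos=2), window=4) == 1.0   # window GGCC
    assert feat.gc_content(g, V(pos=6), window=4) == 0.0   # window ATAT


def test_gc_content_all_n_window_is_missing():
    g = GenomeSequence({"chr1": "NNNNN"})
    assert math.isnan(feat.gc_content(g, V(pos=3, ref="A"), window=3))


def test_gc_content_outside_chromosome_raises():
    g = GenomeSequence({"chr1": "ACGT"})
    with pytest.raises(ValueError):
        feat.gc_content(g, V(pos=10), window=4)


def test_gc_content_matches_counting_oracle(rng):
    g = random_genome(rng)
    seq = g.sequence("chr1")
    for _ in range(100):
        pos = int(rng.integers(1, 2001))
        window = int(rng.integers(1, 200))
        start = pos - 1 - (window - 1) // 2
        chunk = seq[max(0, start):min(2000, start + window)]
        expected = sum(b in "GC" for b in chunk) / len(chunk)
        assert feat.gc_content(g, V(pos=pos), window) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# local_mutation_frequency
# ---------------------------------------------------------------------------

def test_mutation_frequency_excludes_self():
    center = V(pos=1000)
    catalog = [V(pos=600), center, V(pos=1450)]
    assert feat.local_mutation_frequency(center, catalog, window=1000) == 2
    assert feat.local_mutation_frequency(center, [], window=1000) == 0


def test_mutation_frequency_brute_force_oracle(rng):
    catalog = [V(chrom=f"chr{rng.integers(1, 3)}", pos=int(p))
               for p in rng.integers(1, 20_000, 1000)]
    for q in rng.choice(len(catalog), 50, replace=False):
        query = catalog[q]
        expected = sum(
            1 for c in catalog
            if c is not catalog[q]
            and c.chrom == query.chrom and abs(c.pos - query.pos) <= 500
            and (c.pos, c.ref, c.alt) != (query.pos, query.ref, query.alt)
        )
        assert feat.local_mutation_frequency(query, catalog, 1000) == expected


def test_mutation_frequency_matrix_agrees_with_scalar(rng):
    catalog = [V(pos=int(p)) for p in rng.integers(1, 5000, 300)]
    queries = catalog[:40]
    mat = feat._mutfreq_matrix(queries, catalog, 1000)
    for i, q in enumerate(queries):
        assert mat[i, 0] == feat.local_mutation_frequency(q, catalog, 1000)


def test_mutation_frequency_monotone_in_window(rng):
    catalog = [V(pos=int(p)) for p in rng.integers(1, 5000, 500)]
    q = V(pos=2500)
    counts = [feat.local_mutation_frequency(q, catalog, w) for w in (100, 500, 1000, 4000)]
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

def test_spectrum_small_examples():
    g = GenomeSequence({"chr1": "ACGA"})
    vec = feat.spectrum(g, V(pos=2, ref="C", alt="T"), k=2, window=4)
    idx = feat._kmer_index(2)
    assert vec[idx["AC"]] == vec[idx["CG"]] == vec[idx["GA"]] == pytest.approx(1 / 3)
    assert vec.sum() == pytest.approx(1.0)

    homo = GenomeSequence({"chr1": "AAAA"})
    vec = feat.spectrum(homo, V(pos=2, ref="A", alt="T"), k=2, window=4)
    assert vec[idx["AA"]] == 1.0 and vec.sum() == 1.0


def test_spectrum_window_smaller_than_k_rejected():
    g = GenomeSequence({"chr1": "ACGT"})
    with pytest.raises(Exception):
        feat.spectrum(g, V(pos=2), k=3, window=2)


def test_spectrum_matches_sliding_window_oracle(rng):
    g = random_genome(rng, 500)
    seq = g.sequence("chr1")
    k = 3
    for _ in range(100):
        pos = int(rng.integers(1, 501))
        window = int(rng.integers(k, 60))
        start = pos - 1 - (window - 1) // 2
        chunk = seq[max(0, start):min(500, start + window)]
        counts = {}
        for i in range(len(chunk) - k + 1):
            counts[chunk[i:i + k]] = counts.get(chunk[i:i + k], 0) + 1
        total = sum(counts.values())
        vec = feat.spectrum(g, V(pos=pos), k, window)
        assert vec.sum() == pytest.approx(1.0)
        for kmer, j in feat._kmer_index(k).items():
            assert vec[j] == pytest.approx(counts.get(kmer, 0) / total)


# ---------------------------------------------------------------------------
# proximity
# ---------------------------------------------------------------------------

def _interval_set(rows):
    s = IntervalSet()
    for chrom, a, b, kind in rows:
        s.add(GenomicInterval(chrom, a, b, kind))
    return s


def test_proximity_examples():
    ann = _interval_set([("chr1", 199, 210, "TSS"), ("chr1", 95, 105, "splice_site")])
    v = V(pos=100)
    d = feat.proximity_features(v, ann, ["TSS", "splice_site"], log_distance=False)
    assert d[0] == 100.0  # 1-based 100 -> 0-based 99; nearest TSS base at 199
    assert d[1] == 0.0    # inside the splice-site interval
    logd = feat.proximity_features(v, ann, ["TSS"], log_distance=True)
    assert logd[0] == pytest.approx(math.log1p(100))


def test_proximity_unknown_kind_rejected():
    with pytest.raises(Exception):
        feat.proximity_features(V(), IntervalSet(), ["nonsense"])


def test_proximity_missing_when_kind_absent():
    assert math.isnan(feat.proximity_features(V(), IntervalSet(), ["TSS"])[0])


def test_proximity_brute_force_oracle(rng):
    rows = [("chr1", int(s), int(s) + int(rng.integers(1, 50)), kind)
            for kind in ("TSS", "TFBS") for s in rng.integers(0, 100_000, 80)]
    ann = _interval_set(rows)
    for pos in rng.integers(1, 100_000, 500):
        v = V(pos=int(pos))
        got = feat.proximity_features(v, ann, ["TSS", "TFBS"], log_distance=False)
        for j, kind in enumerate(["TSS", "TFBS"]):
            dists = [0 if a <= pos - 1 < b else min(abs(pos - 1 - a), abs(pos - 1 - (b - 1)))
                     for c, a, b, kk in rows if kk == kind]
            assert got[j] == min(dists)


def test_proximity_symmetric_under_reflection(rng):
    length = 10_000
    rows = [("chr1", int(s), int(s) + 10, "TSS") for s in rng.integers(0, length - 10, 30)]
    ann = _interval_set(rows)
    mirrored = _interval_set([("chr1", length - b, length - a, k) for _, a, b, k in rows])
    for pos in rng.integers(1, length + 1, 100):
        v = V(pos=int(pos))
        vm = V(pos=length - int(pos) + 1)
        d = feat.proximity_features(v, ann, ["TSS"], log_distance=False)
        dm_ = feat.proximity_features(vm, mirrored, ["TSS"], log_distance=False)
        assert d[0] == dm_[0]


# ---------------------------------------------------------------------------
# tracks and functional elements
# ---------------------------------------------------------------------------

def test_track_features_value_and_missing():
    track = ScoreTrack.from_intervals([("chr1", 99, 100, 0.9)])
    v = V(pos=100)
    vals = feat.track_features(v, {"cons": track})
    assert vals[0] == 0.9
    assert math.isnan(feat.track_features(V(pos=50), {"cons": track})[0])


def test_functional_element_indicators():
    elems = IntervalSet()
    elems.add(GenomicInterval("chr1", 90, 120, "functional_element", label="enhancer_like"))
    elems.add(GenomicInterval("chr1", 95, 130, "functional_element", label="promoter_like"))
    classes = ["enhancer_like", "promoter_like"]
    assert feat.functional_element_features(V(pos=100), elems, classes).tolist() == [1, 1]
    assert feat.functional_element_features(V(pos=125), elems, classes).tolist() == [0, 1]
    assert feat.functional_element_features(V(pos=500), elems, classes).tolist() == [0, 0]


# ---------------------------------------------------------------------------
# assemble / imputation
# ---------------------------------------------------------------------------

def _group(name, X):
    return feat.FeatureGroupMatrix(name, np.asarray(X, float),
                                   [f"{name}{i}" for i in range(np.shape(X)[1])])


def test_assemble_concatenates_in_group_order(rng):
    a = _group("A", rng.normal(size=(10, 3)))
    b = _group("B", rng.normal(size=(10, 5)))
    X, _ = feat.assemble({"A": a, "B": b}, ["A", "B"])
    assert X.shape == (10, 8)
    assert np.allclose(X[:, :3], a.X) and np.allclose(X[:, 3:], b.X)


def test_assemble_row_misalignment_rejected(rng):
    a = _group("A", rng.normal(size=(10, 2)))
    b = _group("B", rng.normal(size=(11, 2)))
    with pytest.raises(ValueError):
        feat.assemble({"A": a, "B": b}, ["A", "B"])


def test_train_mean_imputation_uses_training_rows_only(rng):
    X = rng.normal(size=(20, 4))
    X[5, 1] = np.nan
    X[15, 2] = np.nan
    g = _group("A", X)
    train = np.arange(10)
    out, fill = feat.assemble({"A": g}, ["A"], train_rows=train)
    expected_mean = np.nanmean(X[:10], axis=0)
    assert np.allclose(fill, expected_mean)
    assert out[5, 1] == pytest.approx(expected_mean[1])
    assert out[15, 2] == pytest.approx(expected_mean[2])
    # leakage: perturbing held-out rows must not change imputation values
    X2 = X.copy()
    X2[12:] += 100.0
    _, fill2 = feat.assemble({"A": _group("A", X2)}, ["A"], train_rows=train)
    assert np.allclose(fill, fill2)
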