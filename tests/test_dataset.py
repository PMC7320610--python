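"""Recurrence labeling, window matching, LOCO folds and subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import somadriver.dataset as dm
from somadriver.io_formats import GenomicInterval, IntervalSet


def V(chrom="chr1", pos=100, r=1, ref="A", alt="G", region="unassigned"):
    return dm.Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, r=r, region=region)


# ---------------------------------------------------------------------------
# assign_labels
# ---------------------------------------------------------------------------

def test_assign_labels_partitions_by_recurrence():
    variants = [V(pos=p, r=r) for p, r in [(1, 1), (2, 1), (3, 7), (4, 3)]]
    cfg = dm.DatasetConfig(region_mode="coding")  # rho defaults to 7
    pos, neg, exc = dm.assign_labels(variants, cfg)
    assert [v.r for v in pos] == [7]
    assert [v.r for v in neg] == [1, 1]
    assert [v.r for v in exc] == [3]


def test_assign_labels_empty_input():
    cfg = dm.DatasetConfig()
    assert dm.assign_labels([], cfg) == ([], [], [])


def test_assign_labels_counting_oracle(rng):
    variants = [V(pos=i + 1, r=int(r)) for i, r in enumerate(rng.integers(1, 21, 10_000))]
    cfg = dm.DatasetConfig(region_mode="noncoding")  # rho defaults to 8
    pos, neg, exc = dm.assign_labels(variants, cfg)
    rs = np.array([v.r for v in variants])
    assert len(pos) == int((rs >= 8).sum())
    assert len(neg) == int((rs == 1).sum())
    assert len(exc) == len(variants) - len(pos) - len(neg)


@given(st.lists(st.integers(1, 30), max_size=200), st.integers(2, 10), st.integers(2, 10))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_larger_rho_never_increases_positives(rs, rho1, rho2):
    lo, hi = sorted((rho1, rho2))
    variants = [V(pos=i + 1, r=r) for i, r in enumerate(rs)]
    p_lo, _, _ = dm.assign_labels(variants, dm.DatasetConfig(rho=lo))
    p_hi, _, _ = dm.assign_labels(variants, dm.DatasetConfig(rho=hi))
    assert set((v.pos for v in p_hi)) <= set(v.pos for v in p_lo)


def test_rho_below_two_rejected():
    with pytest.raises(dm.ConfigError):
        dm.DatasetConfig(rho=1)


def test_region_mode_defaults():
    coding = dm.DatasetConfig(region_mode="coding")
    noncoding = dm.DatasetConfig(region_mode="noncoding")
    assert (coding.rho, coding.window) == (7, 10_000)
    assert (noncoding.rho, noncoding.window) == (8, 1_000)


# ---------------------------------------------------------------------------
# window_match
# ---------------------------------------------------------------------------

def test_window_boundary_is_inclusive():
    neg = [V(pos=5000)]
    assert dm.window_match(neg, [V(pos=15000, r=9)], w=10_000) == neg
    assert dm.window_match(neg, [V(pos=15001, r=9)], w=10_000) == []


def test_window_match_is_per_chromosome():
    neg = [V(chrom="chr2", pos=100)]
    assert dm.window_match(neg, [V(chrom="chr1", pos=100, r=9)], w=1000) == []


def test_window_match_brute_force_oracle(rng):
    positives = [V(chrom=f"chr{rng.integers(1, 4)}", pos=int(p), r=9)
                 for p in rng.integers(1, 200_000, 100)]
    negatives = [V(chrom=f"chr{rng.integers(1, 4)}", pos=int(p))
                 for p in rng.integers(1, 200_000, 2000)]
    w = 3000
    expected = [n for n in negatives
                if any(p.chrom == n.chrom and abs(p.pos - n.pos) <= w for p in positives)]
    assert dm.window_match(negatives, positives, w) == expected


@given(st.integers(1, 5000), st.integers(1, 5000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_window_match_monotone_in_w(w1, w2):
    rng = np.random.default_rng(7)
    positives = [V(pos=int(p), r=9) for p in rng.integers(1, 50_000, 20)]
    negatives = [V(pos=int(p)) for p in rng.integers(1, 50_000, 200)]
    lo, hi = sorted((w1, w2))
    small = {v.pos for v in dm.window_match(negatives, positives, lo)}
    big = {v.pos for v in dm.window_match(negatives, positives, hi)}
    assert small <= big


def test_build_dataset_invariants(rng):
    variants = [V(chrom=f"chr{rng.integers(1, 5)}", pos=int(p), r=int(r))
                for p, r in zip(rng.integers(1, 100_000, 3000), rng.integers(1, 15, 3000))]
    cfg = dm.DatasetConfig(region_mode="noncoding", rho=8, window=2000)
    ds = dm.build_dataset(variants, cfg)
    for v, l in zip(ds.variants, ds.labels):
        if l == 1:
            assert v.r >= 8
        else:
            assert v.r == 1
            assert any(p.chrom == v.chrom and abs(p.pos - v.pos) <= 2000
                       for p, pl in zip(ds.variants, ds.labels) if pl == 1)
    assert all(1 < v.r < 8 for v in ds.excluded)


# ---------------------------------------------------------------------------
# classify_region
# ---------------------------------------------------------------------------

def _annotation_with_cds(rng, n=50):
    ann = IntervalSet()
    cds = []
    for _ in range(n):
        s = int(rng.integers(0, 50_000))
        e = s + int(rng.integers(50, 500))
        ann.add(GenomicInterval("chr1", s, e, "CDS"))
        cds.append((s, e))
    return ann, cds


def test_classify_region_examples(rng):
    ann, _ = _annotation_with_cds(rng, n=0)
    ann.add(GenomicInterval("chr1", 100, 200, "CDS"))
    assert dm.classify_region(V(pos=150), ann) == "coding"
    assert dm.classify_region(V(chrom="chr9", pos=150), ann) == "noncoding"


def test_classify_region_brute_force_oracle(rng):
    ann, cds = _annotation_with_cds(rng)
    for pos in rng.integers(1, 50_500, 500):
        v = V(pos=int(pos))
        expected = any(s <= pos - 1 < e for s, e in cds)
        assert dm.classify_region(v, ann) == ("coding" if expected else "noncoding")


# ---------------------------------------------------------------------------
# LOCO folds
# ---------------------------------------------------------------------------

def _dataset(chrom_labels):
    variants, labels = [], []
    for i, (chrom, label) in enumerate(chrom_labels):
        variants.append(V(chrom=chrom, pos=i + 1, r=9 if label == 1 else 1))
        labels.append(label)
    return dm.LabeledDataset(variants, np.array(labels), dm.DatasetConfig())


def test_folds_exclude_allosomes():
    ds = _dataset([("chr1", 1), ("chr2", -1), ("chrX", 1), ("chrY", -1), ("chrMT", 1)])
    folds = dm.make_loco_folds(ds)
    assert [f.test_chrom for f in folds] == ["chr1", "chr2"]
    for f in folds:
        involved = set(f.train_idx) | set(f.test_idx)
        assert all(ds.variants[i].chrom not in {"chrX", "chrY", "chrMT"} for i in involved)


def test_folds_partition_autosomal_examples(rng):
    chroms = [f"chr{c}" for c in rng.integers(1, 23, 300)] + ["chrX"] * 10
    ds = _dataset([(c, 1 if rng.random() < 0.5 else -1) for c in chroms])
    folds = dm.make_loco_folds(ds)
    test_union = np.concatenate([f.test_idx for f in folds])
    autosomal = [i for i, v in enumerate(ds.variants) if v.chrom != "chrX"]
    assert sorted(test_union) == autosomal
    for f in folds:
        assert not set(f.train_idx) & set(f.test_idx)


def test_single_autosome_fold_is_degenerate():
    ds = _dataset([("chr1", 1), ("chr1", -1)])
    with pytest.warns(UserWarning, match="empty training set"):
        folds = dm.make_loco_folds(ds)
    assert len(folds) == 1 and folds[0].degenerate


def test_no_autosomes_raises():
    ds = _dataset([("chrX", 1)])
    with pytest.raises(dm.DegenerateDataError):
        dm.make_loco_folds(ds)


# ---------------------------------------------------------------------------
# balanced_subsample
# ---------------------------------------------------------------------------

def test_balanced_subsample_sizes_and_determinism(rng):
    labels = np.concatenate([np.ones(10_000, int), -np.ones(9000, int)])
    idx1 = dm.balanced_subsample_idx(labels, 4000, seed=5)
    idx2 = dm.balanced_subsample_idx(labels, 4000, seed=5)
    idx3 = dm.balanced_subsample_idx(labels, 4000, seed=6)
    assert (labels[idx1] == 1).sum() == 4000 and (labels[idx1] == -1).sum() == 4000
    assert np.array_equal(idx1, idx2)
    assert not np.array_equal(idx1, idx3)


def test_subsample_larger_than_classes_warns_and_keeps_all():
    labels = np.array([1] * 5 + [-1] * 3)
    with pytest.warns(UserWarning, match="exceeds both class sizes"):
        idx = dm.balanced_subsample_idx(labels, 100, seed=0)
    assert len(idx) == 8


def test_subsample_requires_both_classes():
    with pytest.raises(dm.DegenerateDataError):
        dm.balanced_subsample_idx(np.ones(10, int), 5, seed=0)
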