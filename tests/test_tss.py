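"""TSS cluster calling, refinement, reproducibility filtering, regions."""

import numpy as np
import pandas as pd
import pytest

from isote import (
    TagTrack,
    TssCluster,
    assign_region,
    call_clusters,
    fit_idr,
    idr_filter,
    local_background,
    refine_cluster,
)
from isote.io import Annotation, CoverageTrack, Transcript
from isote.tss import match_clusters


def make_track(positions, counts, chrom="chr1", strand="+"):
    order = np.argsort(positions)
    return TagTrack({
        (chrom, strand): (np.asarray(positions)[order],
                          np.asarray(counts, float)[order])
    })


def make_coverage(start, end, value, chrom="chr1"):
    return CoverageTrack(pd.DataFrame(
        [dict(chrom=chrom, start0=start, end0=end, value=value)]
    ))


# ---------------------------------------------------------------------------
# local background
# ---------------------------------------------------------------------------


def test_local_background_uniform_tags():
    pos = np.arange(1000, 3000)
    track = make_track(pos, np.full(len(pos), 3.0))
    bg = local_background(track, None, "chr1", "+", 2000)
    assert bg[0] == pytest.approx(3.0)


def test_local_background_expression_floor():
    track = make_track([10_000], [1.0])
    cov = make_coverage(0, 20_000, 4.0)
    bg = local_background(track, cov, "chr1", "+", 5000, depth_norm=1.0)
    assert bg[0] == pytest.approx(4.0)
    bg_scaled = local_background(track, cov, "chr1", "+", 5000, depth_norm=0.5)
    assert bg_scaled[0] == pytest.approx(2.0)


def test_local_background_single_tower():
    track = make_track([5000], [50.0])
    bg = local_background(track, None, "chr1", "+", 5000)
    assert bg[0] == pytest.approx(50.0 / 500)
    cov = make_coverage(0, 10_000, 1.0)
    bg2 = local_background(track, cov, "chr1", "+", 5000)
    assert bg2[0] == pytest.approx(max(50.0 / 500, 1.0))


# ---------------------------------------------------------------------------
# cluster calling and refinement
# ---------------------------------------------------------------------------


def test_call_clusters_empty_track():
    assert call_clusters(TagTrack({}), None) == []


def test_call_clusters_merges_within_20nt():
    track = make_track([1000, 1015], [50.0, 30.0])
    clusters = call_clusters(track, None)
    assert len(clusters) == 1
    c = clusters[0]
    assert (c.start0, c.end0) == (1000, 1016)
    assert c.summit == 1000
    assert c.pooled_count == 80.0


def test_call_clusters_splits_beyond_20nt():
    track = make_track([1000, 1050], [50.0, 30.0])
    clusters = call_clusters(track, None)
    assert len(clusters) == 2
    assert [c.summit for c in clusters] == [1000, 1050]


def test_summit_tie_breaks_to_most_5prime():
    plus = call_clusters(make_track([1000, 1005], [40.0, 40.0]), None)[0]
    assert plus.summit == 1000
    minus = call_clusters(make_track([1000, 1005], [40.0, 40.0], strand="-"), None)[0]
    assert minus.summit == 1005


def _cluster_from(positions, counts, strand="+"):
    positions = np.asarray(positions)
    counts = np.asarray(counts, float)
    best = counts.max()
    tied = positions[counts == best]
    summit = int(tied.min() if strand == "+" else tied.max())
    return TssCluster("chr1", strand, int(positions[0]), int(positions[-1]) + 1,
                      summit, float(counts.sum()), positions, counts)


def test_refine_short_cluster_is_identity():
    c = _cluster_from(np.arange(100, 180), np.full(80, 5.0))
    assert refine_cluster(c, bg=1.0) == [c]


def test_refine_splits_towers_joined_by_plateau():
    pos = np.arange(0, 150)
    counts = np.full(150, 1.2)          # plateau just above bg = 1
    counts[:10] = 8.0                   # sharp 5' tower
    counts[140:] = 6.0                  # sharp 3' tower
    parent = _cluster_from(pos, counts)
    parts = refine_cluster(parent, bg=1.0)
    assert len(parts) == 2
    assert all(p.length <= 100 for p in parts)
    assert not any(p.flagged for p in parts)
    assert parts[0].summit == parent.summit


def test_refine_flat_plateau_is_flagged():
    c = _cluster_from(np.arange(0, 150), np.full(150, 10.0))  # 10x bg everywhere
    parts = refine_cluster(c, bg=1.0)
    assert len(parts) == 1
    assert parts[0].flagged
    assert parts[0].length == 150


def test_refinement_never_grows_or_drops_summit(rng):
    for _ in range(20):
        n = int(rng.integers(110, 300))
        pos = np.arange(0, n)
        counts = rng.uniform(1.1, 12.0, n)
        parent = _cluster_from(pos, counts)
        parts = refine_cluster(parent, bg=1.0)
        assert sum(p.length for p in parts) <= parent.length
        assert any(p.start0 <= parent.summit < p.end0 for p in parts)


# ---------------------------------------------------------------------------
# IDR
# ---------------------------------------------------------------------------


def _simulated_signals(rng, n_real=150, n_noise=150):
    z = rng.lognormal(3.0, 1.0, n_real)
    s1 = z * np.exp(rng.normal(0, 0.15, n_real))
    s2 = z * np.exp(rng.normal(0, 0.15, n_real))
    n1 = rng.lognormal(1.0, 1.0, n_noise)
    n2 = rng.lognormal(1.0, 1.0, n_noise)
    return np.concatenate([s1, n1]), np.concatenate([s2, n2]), z


def test_idr_separates_reproducible_from_noise(rng):
    x, y, z = _simulated_signals(rng)
    fit = fit_idr(x, y)
    top = np.argsort(-z)[:50]  # strongest truly reproducible pairs
    assert np.all(fit.local_idr[top] < 0.05)
    assert fit.rho > 0.5


def test_idr_shuffled_signals_are_irreproducible(rng):
    x, y, _ = _simulated_signals(rng)
    fit = fit_idr(x, rng.permutation(y))
    assert np.mean(fit.local_idr > 0.05) >= 0.90


def test_idr_rank_invariance(rng):
    x, y, _ = _simulated_signals(rng)
    f1 = fit_idr(x, y)
    f2 = fit_idr(np.log(x), y**0.3)  # monotone transforms
    np.testing.assert_allclose(f1.local_idr, f2.local_idr, atol=1e-9)


def test_idr_requires_enough_pairs():
    with pytest.raises(ValueError, match="fallback"):
        fit_idr(np.arange(5.0), np.arange(5.0))


def _singleton(pos, count, strand="+"):
    return _cluster_from([pos], [count], strand)


def test_unmatched_cluster_is_excluded():
    rep1 = [_singleton(100, 50), _singleton(5000, 40)]
    rep2 = [_cluster_from([99, 100, 101], [20, 45, 15])]
    pairs = match_clusters(rep1, rep2)
    assert len(pairs) == 1
    assert pairs[0][0].summit == 100


def test_idr_filter_fallback_mode():
    rep1 = [_singleton(100, 50), _singleton(5000, 5)]
    rep2 = [_singleton(100, 45), _singleton(5000, 5)]
    kept = idr_filter(rep1, rep2, mode="fallback", min_count=20)
    assert len(kept) == 1 and kept[0][0].summit == 100


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------


@pytest.fixture
def annotation():
    # plus-strand gene: tx 2000-6000, annotated TSS 2000, start codon 2500,
    # CDS 2500-5000 with an intron 3000-4000, 3'UTR 5000-6000
    tx = Transcript("t1", "gA", "chr1", "+", 2000, 6000, 2500, 5000,
                    [(2000, 3000), (4000, 6000)])
    genes = pd.DataFrame([
        dict(gene="gA", chrom="chr1", strand="+", tss0=2000, start_codon0=2500,
             orf_length=1500),
    ])
    return Annotation([tx], genes)


@pytest.mark.parametrize(
    "summit, region, gene",
    [
        (2200, "annotated-5UTR", "gA"),
        (1700, "up-1kb", "gA"),      # 300 nt upstream of the annotated TSS
        (500, "intergenic", None),   # 1,500 nt upstream, beyond the 1 kb rule
        (2700, "CDS", "gA"),
        (3500, "intron", "gA"),
        (5500, "3UTR", "gA"),
    ],
)
def test_assign_region_precedence(annotation, summit, region, gene):
    c = _singleton(summit, 30)
    got_region, got_gene = assign_region(c, annotation)
    assert got_region == region
    assert got_gene == gene


def test_assign_region_is_strand_aware(annotation):
    c = _singleton(2200, 30, strand="-")
    region, gene = assign_region(c, annotation)
    assert region == "intergenic" and gene is None
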