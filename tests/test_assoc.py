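"""Association statistics: length matching, rank tests, enrichments."""

import numpy as np
import pandas as pd
import pytest

from isote import (
    AUG_FREE_HEXAMERS,
    fisher_direction_enrichment,
    group_compare,
    hexamer_scan,
    match_length_diff,
    top_comparison,
    uorf_dose_response,
)
from oracles import exact_mannwhitney_p_shift


def _records(dlengths, lfcs, **extra):
    df = pd.DataFrame({"dlength": dlengths, "lfc": lfcs})
    for k, v in extra.items():
        df[k] = v
    return df


# ---------------------------------------------------------------------------
# length matching
# ---------------------------------------------------------------------------


def test_match_identical_distributions_returns_intact(rng):
    a = _records([50, 150, 250, 350], [0.0] * 4)
    b = _records([60, 140, 260, 340], [0.0] * 4)
    ma, mb = match_length_diff(a, b, rng=rng)
    assert len(ma) == len(mb) == 4


def test_match_disjoint_bins_errors(rng):
    a = _records([10, 50, 90], [0.0] * 3)
    b = _records([110, 150, 190], [0.0] * 3)
    with pytest.raises(ValueError):
        match_length_diff(a, b, rng=rng)


def test_match_downsamples_to_per_bin_minimum(rng):
    a = _records([50] * 10 + [150] * 5, [0.0] * 15)
    b = _records([50] * 2 + [150] * 20, [0.0] * 22)
    ma, mb = match_length_diff(a, b, rng=rng)
    bins_a = np.digitize(ma["dlength"], np.arange(0, 2001, 100))
    bins_b = np.digitize(mb["dlength"], np.arange(0, 2001, 100))
    assert sorted(np.bincount(bins_a)[np.bincount(bins_a) > 0]) == [2, 5]
    np.testing.assert_array_equal(np.bincount(bins_a), np.bincount(bins_b))


def test_matched_distributions_pass_ks(rng):
    from scipy.stats import ks_2samp

    a = _records(rng.integers(0, 800, 300), np.zeros(300))
    b = _records((rng.integers(0, 800, 300) ** 1.1) % 800, np.zeros(300))
    ma, mb = match_length_diff(a, b, rng=rng)
    binned_a = np.digitize(ma["dlength"], np.arange(0, 2001, 100))
    binned_b = np.digitize(mb["dlength"], np.arange(0, 2001, 100))
    assert ks_2samp(binned_a, binned_b).pvalue > 0.2


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def test_group_compare_identical_groups():
    _, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p > 0.5
    _, p_tied = group_compare([1.0] * 5, [1.0] * 5)
    assert p_tied == 1.0


def test_group_compare_exact_small_sample():
    u, p = group_compare([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)
    assert p == pytest.approx(exact_mannwhitney_p_shift([1, 2, 3], [4, 5, 6]))


def test_group_compare_detects_shift(rng):
    a = rng.normal(0, 1, 50)
    _, p = group_compare(a, a + 1.5)
    assert p < 0.01


def test_group_compare_minimum_sizes():
    with pytest.raises(ValueError):
        group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# uORF dose response
# ---------------------------------------------------------------------------


def test_dose_response_monotone_with_planted_penalty(rng):
    n_uorf = rng.integers(0, 5, 400)
    lfc = -0.8 * n_uorf + rng.normal(0, 0.3, 400)
    res = uorf_dose_response(_records(np.full(400, 100), lfc, n_uorf=n_uorf))
    assert res.strata == ["0", "1", "2", "3+"]
    assert res.monotone_decreasing
    assert res.pairwise_p[("0", "3+")] < 1e-6


def test_dose_response_single_stratum_errors():
    with pytest.raises(ValueError):
        uorf_dose_response(_records([100] * 10, [0.0] * 10, n_uorf=[0] * 10))


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


def test_fisher_perfect_association():
    pairs = _records(
        [100] * 20, [0.0] * 20,
        has_uorf=[True] * 10 + [False] * 10,
        direction=["longer-lower"] * 10 + [""] * 10,
    )
    odds, p, table = fisher_direction_enrichment(pairs, "has_uorf")
    assert np.isinf(odds)
    np.testing.assert_array_equal(table, [[10, 0], [0, 10]])
    # both one-sided extremes of the central hypergeometric
    assert p == pytest.approx(2 / 184756, rel=1e-6)


def test_fisher_independent_proportions():
    pairs = _records(
        [100] * 40, [0.0] * 40,
        has_uorf=([True] * 10 + [False] * 10) * 2,
        direction=(["longer-lower"] * 5 + [""] * 5) * 4,
    )
    _, p, _ = fisher_direction_enrichment(pairs, "has_uorf")
    assert p > 0.5


def test_fisher_degenerate_margin_errors():
    pairs = _records([100] * 10, [0.0] * 10, has_uorf=[True] * 10,
                     direction=["longer-lower"] * 10)
    with pytest.raises(ValueError):
        fisher_direction_enrichment(pairs, "has_uorf")


# ---------------------------------------------------------------------------
# hexamer scan
# ---------------------------------------------------------------------------


def _presence_matrix(n, planted_idx, planted_mask, rng, background=0.02):
    mat = rng.random((n, len(AUG_FREE_HEXAMERS))) < background
    mat[:, planted_idx] = planted_mask
    return mat


def test_hexamer_scan_flags_planted_motif(rng):
    n = 120
    idx = AUG_FREE_HEXAMERS.index("AAUCCC")
    mask = np.arange(n) < 50
    lfc = np.where(mask, -1.5, 0.0) + rng.normal(0, 0.3, n)
    pairs = _records(rng.integers(50, 500, n), lfc)
    mat = _presence_matrix(n, idx, mask, rng)
    res = hexamer_scan(pairs, mat, rng=rng)
    hit = res[res["hexamer"] == "AAUCCC"]
    assert len(hit) == 1
    assert bool(hit["significant"].iloc[0])
    assert int(hit["direction"].iloc[0]) == -1


def test_hexamer_scan_null_has_no_bh_hits(rng):
    n = 100
    pairs = _records(rng.integers(50, 500, n), rng.normal(0, 0.5, n))
    mat = rng.random((n, len(AUG_FREE_HEXAMERS))) < 0.05
    res = hexamer_scan(pairs, mat, rng=rng)
    assert len(res) > 50                    # plenty of testable hexamers
    assert res["significant"].sum() == 0


def test_hexamer_scan_requires_pairs_and_variation(rng):
    pairs = _records([100] * 10, [0.0] * 10)
    with pytest.raises(ValueError):
        hexamer_scan(pairs, np.zeros((10, 3841), bool), rng=rng)
    constant = _records([100] * 30, list(np.linspace(-1, 1, 30)))
    res = hexamer_scan(constant, np.zeros((30, 3841), bool), rng=rng)
    assert len(res) == 0                    # no hexamer varies


# ---------------------------------------------------------------------------
# TOP comparison
# ---------------------------------------------------------------------------


def test_top_control_orientation_is_symmetric(rng):
    ctrl = _records([100] * 400, rng.normal(1.0, 0.2, 400))  # all shifted +1
    top = _records([100] * 5, [0.0] * 5)
    _, ctrl_vals, _ = top_comparison(top, ctrl, rng=rng)
    assert abs(np.mean(ctrl_vals)) < 0.25  # random orientation recenters


def test_top_penalty_detected(rng):
    top = _records([100] * 30, rng.normal(-1.0, 0.3, 30))
    ctrl = _records([100] * 100, rng.normal(0.0, 0.3, 100))
    top_vals, _, p = top_comparison(top, ctrl, rng=rng)
    assert np.median(top_vals) == pytest.approx(-1.0, abs=0.3)
    assert p < 0.001


def test_top_requires_three_genes(rng):
    with pytest.raises(ValueError):
        top_comparison(_records([100], [0.0]), _records([100] * 10, [0.0] * 10),
                       rng=rng)
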