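"""PSI rules, UTR reconstruction, and cis-element feature extraction."""

import numpy as np
import pytest

from isote import (
    AUG_FREE_HEXAMERS,
    SpliceEvent,
    StackingEngine,
    compute_psi,
    count_hexamers,
    detect_top,
    divergent_region,
    find_uorfs,
    fold_windows,
    get_engine,
    reconstruct_utr,
)
from isote.simulate import HAIRPIN, random_background
from oracles import (
    brute_force_aug_classes,
    count_hexamers_with_aug_dp,
    naive_hexamer_counts,
)


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def _event(s_out, s_in, annotation):
    return SpliceEvent("chr1", "+", 100, 200, s_out, s_in, annotation)


@pytest.mark.parametrize(
    "s_out, s_in, annotation, psi, status",
    [
        (0, 0, "constitutive", 0.0, "removed"),      # 0 / (0 + 10 pseudo)
        (0, 0, "alternative", 0.5, "ambiguous"),     # 5 / (5 + 5) pseudo
        (9, 1, "novel", 0.1, "removed"),             # inclusive threshold
        (1, 39, "novel", 0.975, "retained"),
        (5, 5, "novel", 0.5, "ambiguous"),
    ],
)
def test_compute_psi_pseudo_read_rules(s_out, s_in, annotation, psi, status):
    got_psi, got_status = compute_psi(_event(s_out, s_in, annotation))
    assert got_psi == pytest.approx(psi)
    assert got_status == status


def test_compute_psi_novel_without_reads_is_ambiguous():
    psi, status = compute_psi(_event(0, 0, "novel"))
    assert np.isnan(psi) and status == "ambiguous"


def test_splice_event_validation():
    with pytest.raises(ValueError):
        SpliceEvent("chr1", "+", 200, 100, 1, 1, "novel")
    with pytest.raises(ValueError):
        SpliceEvent("chr1", "+", 100, 200, -1, 1, "novel")


# ---------------------------------------------------------------------------
# UTR reconstruction
# ---------------------------------------------------------------------------


@pytest.fixture
def genome(rng):
    return {"chr1": random_background(rng, 2000)}


def test_reconstruct_plain_span(genome):
    m = reconstruct_utr("i", "chr1", "+", 100, 400, [], genome)
    assert m.status == "resolved"
    assert m.sequence == genome["chr1"][100:400].replace("T", "U")
    assert m.length == 300


def test_reconstruct_removes_constitutive_intron(genome):
    ev = SpliceEvent("chr1", "+", 200, 288, 40, 0, "constitutive")  # 88-nt intron
    m = reconstruct_utr("i", "chr1", "+", 100, 400, [ev], genome)
    assert m.length == 300 - 88
    expect = (genome["chr1"][100:200] + genome["chr1"][288:400]).replace("T", "U")
    assert m.sequence == expect


def test_reconstruct_ambiguous_event_excludes_isoform(genome):
    ev = SpliceEvent("chr1", "+", 200, 288, 0, 0, "alternative")  # PSI 0.5
    m = reconstruct_utr("i", "chr1", "+", 100, 400, [ev], genome)
    assert m.status == "ambiguous-excluded"
    assert m.sequence == ""


def test_reconstruct_minus_strand(genome):
    from isote.utr import revcomp

    m = reconstruct_utr("i", "chr1", "-", 900, 599, [], genome)
    assert m.sequence == revcomp(genome["chr1"][600:901]).replace("T", "U")


def test_reconstruct_rejects_downstream_tss(genome):
    with pytest.raises(ValueError):
        reconstruct_utr("i", "chr1", "+", 500, 400, [], genome)


# ---------------------------------------------------------------------------
# uORF / uAUG / TOP scanning against brute-force oracles
# ---------------------------------------------------------------------------


def test_find_uorfs_worked_examples():
    assert find_uorfs("ATGAAATAA" + "CCCCCC") == (1, 0, 0)
    # AUG 9 nt before the main AUG, no stop in the UTR -> in-frame uAUG
    assert find_uorfs("CCC" + "ATG" + "CCCCCC") == (0, 1, 0)
    assert find_uorfs("CCC" + "ATG" + "CCCCC") == (0, 0, 1)
    assert find_uorfs("CACCGCCACC") == (0, 0, 0)


def test_find_uorfs_matches_brute_force_on_random_sequences(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 300))
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
        assert find_uorfs(seq) == brute_force_aug_classes(seq)


def test_find_uorfs_rejects_non_nucleotides():
    with pytest.raises(ValueError):
        find_uorfs("ACGTN")


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("CUUUCAAA", True),
        ("CTTCTCGGG", True),
        ("CAAAAGGG", False),
        ("UUUUUAAA", False),   # cap site must be C
        ("CUUU", False),       # too short for 4 pyrimidines
    ],
)
def test_detect_top(seq, expected):
    assert detect_top(seq) is expected


# ---------------------------------------------------------------------------
# hexamers
# ---------------------------------------------------------------------------


def test_aug_free_hexamer_universe_size():
    assert len(AUG_FREE_HEXAMERS) == 4096 - count_hexamers_with_aug_dp()
    assert len(AUG_FREE_HEXAMERS) == 3841
    assert all("AUG" not in h for h in AUG_FREE_HEXAMERS)


def test_count_hexamers_short_sequence_is_zero():
    assert count_hexamers("ACGUA").sum() == 0


def test_count_hexamers_single_planted_motif():
    seq = "CCCCCCCC" + "AAAAAU" + "GGGGGGGG"
    counts = count_hexamers(seq)
    assert counts[AUG_FREE_HEXAMERS.index("AAAAAU")] == 1


def test_count_hexamers_matches_naive_scan(rng):
    for _ in range(50):
        n = int(rng.integers(6, 400))
        seq = "".join("ACGU"[b] for b in rng.integers(0, 4, n))
        counts = count_hexamers(seq)
        naive = naive_hexamer_counts(seq)
        for h, c in naive.items():
            if "AUG" in h:
                continue
            assert counts[AUG_FREE_HEXAMERS.index(h)] == c
        # total = number of AUG-free windows
        n_windows = sum(c for h, c in naive.items() if "AUG" not in h)
        assert counts.sum() == n_windows


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------


def test_polya_window_is_unstructured():
    for engine in (StackingEngine(), get_engine("vienna")):
        prof = fold_windows("A" * 50, engine)
        assert prof.cap_mfe == pytest.approx(0.0, abs=0.2)
        assert not prof.cap_stable


def test_gc_hairpin_in_cap_window_is_stable_thermodynamically(rng):
    seq = HAIRPIN + random_background(rng, 60)
    prof = fold_windows(seq, get_engine("vienna"))
    assert prof.cap_mfe < -30.0
    assert prof.cap_stable


def test_efe_never_exceeds_mfe(rng):
    engine = get_engine("vienna")
    for _ in range(10):
        seq = "".join("ACGU"[b] for b in rng.integers(0, 4, 50)) + HAIRPIN
        prof = fold_windows(seq, engine, step=10)
        assert prof.cap_efe <= prof.cap_mfe + 1e-6
        assert prof.min_window_efe <= prof.min_window_mfe + 1e-6


def test_builtin_engine_ranks_hairpin_below_random(rng):
    engine = StackingEngine()
    hairpin_mfe, _ = engine.fold(HAIRPIN)
    random_mfe, _ = engine.fold("".join("ACGU"[b] for b in rng.integers(0, 4, 32)))
    assert hairpin_mfe < random_mfe


# ---------------------------------------------------------------------------
# divergent region
# ---------------------------------------------------------------------------


def test_divergent_region_suffix_sharing():
    assert divergent_region("AAACCCGGG", "CCCGGG") == "AAACCC"[:3]
    assert divergent_region("AAACCC", "AAACCC") == ""
    assert divergent_region("AAACCC", "GGGCCC") is None
    with pytest.raises(ValueError):
        divergent_region("CCC", "AAACCC")


def test_divergent_region_uses_mature_not_genomic_sequence(genome):
    # an 88-nt intron inside the long isoform's extra span is spliced out:
    # the divergent region must come from the mature sequences
    ev = SpliceEvent("chr1", "+", 150, 238, 40, 0, "constitutive")
    long_m = reconstruct_utr("L", "chr1", "+", 100, 500, [ev], genome)
    short_m = reconstruct_utr("S", "chr1", "+", 300, 500, [ev], genome)
    div = divergent_region(long_m, short_m)
    naive_genomic = genome["chr1"][100:300].replace("T", "U")
    assert div is not None
    assert len(div) == 200 - 88
    assert div != naive_genomic
    assert div == (genome["chr1"][100:150] + genome["chr1"][238:300]).replace("T", "U")
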