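"""Synthetic-data generator: round trips, fraction mapping, reproducibility."""

import numpy as np
import pytest

from isote import (
    SimConfig,
    detect_top,
    find_uorfs,
    fold_windows,
    get_engine,
    plant_utr_features,
    simulate_dataset,
)
from isote.simulate import (
    FeaturePlantingError,
    _load_to_fraction,
    expected_ribosomes_per_mrna,
    random_background,
)
from isote.quant import RIBOSOME_WEIGHTS
from oracles import truncated_poisson_expected_load


# ---------------------------------------------------------------------------
# background sequence and feature planting
# ---------------------------------------------------------------------------


def test_background_is_aug_and_stop_free(rng):
    seq = random_background(rng, 2000)
    for motif in ("ATG", "TAA", "TAG", "TGA"):
        assert motif not in seq


def test_plant_uorf_round_trip(rng):
    seq = plant_utr_features(random_background(rng, 200), ["uorf"], rng)
    assert find_uorfs(seq) == (1, 0, 0)


def test_plant_top_round_trip(rng):
    seq = plant_utr_features(random_background(rng, 100), ["top"], rng)
    assert detect_top(seq)
    plain = plant_utr_features(random_background(rng, 100), [], rng)
    assert not detect_top(plain)


def test_plant_hairpin_gives_stable_cap_window(rng):
    seq = plant_utr_features(random_background(rng, 150), ["structure"], rng)
    assert fold_windows(seq, get_engine("vienna")).cap_stable


def test_plant_uaug_frames_respect_downstream_length(rng):
    downstream = random_background(rng, 101)
    seq_in = plant_utr_features(random_background(rng, 150), ["uaug_in"], rng,
                                downstream_seq=downstream)
    assert find_uorfs(seq_in + downstream) == (0, 1, 0)
    seq_out = plant_utr_features(random_background(rng, 150), ["uaug_out"], rng,
                                 downstream_seq=downstream)
    assert find_uorfs(seq_out + downstream) == (0, 0, 1)


def test_plant_combined_features_round_trip(rng):
    feats = ["top", "structure", "uorf", "uorf", "uaug_out", ("hexamer", "AATCCC")]
    seq = plant_utr_features(random_background(rng, 400), feats, rng)
    assert find_uorfs(seq) == (2, 0, 1)
    assert detect_top(seq)
    assert "AATCCC" in seq


def test_plant_insufficient_length_raises(rng):
    with pytest.raises(FeaturePlantingError):
        plant_utr_features(random_background(rng, 30), ["uorf", "uorf", "uorf"], rng)


# ---------------------------------------------------------------------------
# ribosome-load to fraction mapping
# ---------------------------------------------------------------------------


def test_zero_load_splits_between_free_fractions(rng):
    frac = _load_to_fraction(np.zeros(10_000, dtype=int), rng)
    assert set(np.unique(frac)) == {0, 1}
    assert abs(frac.mean() - 0.5) < 0.05


def test_truncated_poisson_oracle_agreement(rng):
    """Monte-Carlo fraction split matches the enumerated expectation."""
    for lam in (0.5, 2.0, 6.0, 12.0):
        k = np.minimum(rng.poisson(lam, 200_000), 12)
        frac = _load_to_fraction(k, rng)
        estimate = RIBOSOME_WEIGHTS[frac].mean()
        oracle = truncated_poisson_expected_load(lam)
        assert estimate == pytest.approx(oracle, rel=0.02)
        assert expected_ribosomes_per_mrna(lam) == pytest.approx(oracle, rel=1e-9)


def test_heavy_load_lands_in_heaviest_fraction(rng):
    k = np.minimum(rng.poisson(12.0, 50_000), 12)
    frac = _load_to_fraction(k, rng)
    assert (frac == 6).mean() > 0.75
    assert RIBOSOME_WEIGHTS[frac].mean() == pytest.approx(
        truncated_poisson_expected_load(12.0), rel=0.02
    )


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------


def test_same_seed_gives_identical_outputs():
    a = simulate_dataset(SimConfig(n_genes=6, seed=42))
    b = simulate_dataset(SimConfig(n_genes=6, seed=42))
    assert a.genome == b.genome
    assert a.tags.to_csv() == b.tags.to_csv()
    assert a.spikes.to_csv() == b.spikes.to_csv()
    assert a.truth.isoforms.to_csv() == b.truth.isoforms.to_csv()
    c = simulate_dataset(SimConfig(n_genes=6, seed=43))
    assert a.tags.to_csv() != c.tags.to_csv()


def test_zero_load_dataset_fills_only_free_fractions():
    cfg = SimConfig(n_genes=5, seed=3, ribosome_lambda_range=(0.0, 0.0),
                    background_rate=0.0)
    ds = simulate_dataset(cfg)
    assert set(ds.tags["fraction"].unique()) <= {1, 2}


def test_clean_conditions_emit_tags_at_true_tss_only():
    cfg = SimConfig(
        n_genes=5, seed=4, background_rate=0.0, tag_scatter=0.0,
        spike_factors=np.ones((2, 7)), splice_prob=0.0,
    )
    ds = simulate_dataset(cfg)
    true_tss = set(ds.truth.isoforms["tss0"])
    assert set(ds.tags["pos0"]) <= true_tss


def test_truth_features_recoverable_from_emitted_utrs():
    ds = simulate_dataset(SimConfig(n_genes=40, seed=5))
    checked = 0
    for _, row in ds.truth.isoforms.iterrows():
        if row["utr_status"] != "resolved":
            continue
        feats = [f for f in str(row["features"]).split(",") if f]
        n_uorf, n_in, n_out = find_uorfs(row["utr_seq"])
        assert n_uorf == sum(f == "uorf" for f in feats)
        assert n_in == sum(f == "uaug_in" for f in feats)
        assert n_out == sum(f == "uaug_out" for f in feats)
        assert detect_top(row["utr_seq"]) == ("top" in feats)
        for f in feats:
            if f.startswith("hexamer:"):
                assert f.split(":")[1].replace("T", "U") in row["utr_seq"]
        checked += 1
    assert checked > 20


def test_config_validation():
    with pytest.raises(ValueError):
        simulate_dataset(SimConfig(n_genes=0))
    with pytest.raises(ValueError):
        SimConfig(tss_per_gene_probs={1: 0.5, 2: 0.2}).validate()
    with pytest.raises(ValueError):
        SimConfig(spike_factors=np.ones((2, 6))).validate()
    with pytest.raises(ValueError):
        SimConfig(background_rate=-1.0).validate()


def test_estimator_consistency_under_clean_conditions(rng):
    """With no background/scatter/distortion and deep sampling, counting tags
    at the true TSS reproduces the truncated-Poisson load within 2%."""
    cfg = SimConfig(
        n_genes=8, seed=6, background_rate=0.0, tag_scatter=0.0,
        spike_factors=np.ones((2, 7)), splice_prob=0.0,
        abundance_law=(np.log(12_000.0), 0.01),
    )
    ds = simulate_dataset(cfg)
    tags = ds.tags[ds.tags["replicate"] == 1]
    by_pos = tags.groupby(["pos0", "fraction"])["count"].sum()
    checked = 0
    for _, iso in ds.truth.isoforms.iterrows():
        counts = np.array([
            by_pos.get((iso["tss0"], j), 0.0) for j in range(1, 8)
        ], dtype=float)
        if counts.sum() < 10_000:
            continue  # overlapping isoform positions are skipped
        estimate = RIBOSOME_WEIGHTS @ counts / counts.sum()
        expected = truncated_poisson_expected_load(iso["lam"])
        assert estimate == pytest.approx(expected, rel=0.02)
        checked += 1
    assert checked >= 10
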