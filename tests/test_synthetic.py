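"""Generators: determinism, truth records, and closure with the analyzers."""

import math

import numpy as np
import pytest

from fuzzbind.observables import Ensemble, pre_profile, rg_distribution
from fuzzbind.synthetic import (TruthRecord, gen_chain_ensemble,
                                gen_pre_truth, gen_rna_conformers,
                                gen_titration, gen_turbidity,
                                realized_bend_deg)
from fuzzbind.binding import anisotropy_model


def test_same_seed_reproduces_everything(tar):
    for maker in (lambda s: gen_titration(1e-6, seed=s)[0].anisotropy,
                  lambda s: gen_chain_ensemble(20, n_frames=5, seed=s)[0].coords,
                  lambda s: gen_rna_conformers(tar, n_conformers=3, seed=s)[0].coords,
                  lambda s: gen_turbidity(seed=s)[0].a340):
        a, b, c = maker(5), maker(5), maker(6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


def test_truth_record_roundtrip(tmp_path):
    _, rec = gen_titration(0.67e-6, seed=9)
    path = tmp_path / "truth.json"
    rec.to_json(path)
    back = TruthRecord.from_json(path)
    assert back.generator == rec.generator
    assert back.seed == 9
    assert back.params["kd"] == pytest.approx(0.67e-6)


def test_noiseless_titration_lies_on_model_curve():
    s, rec = gen_titration(1e-6, noise_sd=0.0, seed=0)
    model = anisotropy_model(rec.params["probe"], s.titrant_totals,
                             {"kd": 1e-6, "r_free": rec.params["r_free"],
                              "r_bound": rec.params["r_bound"]})
    np.testing.assert_allclose(s.anisotropy, model, rtol=1e-12)


def test_replicate_sd_matches_sampling_statistics():
    """E[s] for n=3 replicates is c4 * sigma with c4(3) ~ 0.8862."""
    sds = []
    for seed in range(30):
        s, _ = gen_titration(1e-6, noise_sd=0.002, replicates=3,
                             n_points=16, seed=seed)
        sds.append(s.replicate_sd)
    c4 = math.sqrt(2.0 / 2.0) * math.gamma(1.5) / math.gamma(1.0)
    assert np.mean(sds) == pytest.approx(c4 * 0.002, rel=0.05)


def test_chain_ensemble_rg_matches_ideal_chain_closed_form():
    b = 6.18
    ens, _ = gen_chain_ensemble(68, bond_b=b, n_frames=1200, seed=6)
    rms_rg = math.sqrt(np.mean(rg_distribution(ens).rg ** 2))
    assert rms_rg == pytest.approx(b * math.sqrt(68 / 6.0), rel=0.03)


def test_compaction_scales_all_distances():
    e1, _ = gen_chain_ensemble(15, n_frames=20, seed=8, compaction=1.0)
    e2, _ = gen_chain_ensemble(15, n_frames=20, seed=8, compaction=0.5)
    np.testing.assert_allclose(e2.coords, 0.5 * e1.coords)


def test_helix_region_validation():
    with pytest.raises(ValueError):
        gen_chain_ensemble(10, helix_region=(5, 15, 0.5))
    with pytest.raises(ValueError):
        gen_chain_ensemble(10, helix_region=(2, 8, 1.5))


def test_conformer_bend_statistics(tar):
    conf, _ = gen_rna_conformers(tar, bend_deg=52.0, jitter_deg=8.0,
                                 n_conformers=150, seed=12)
    bends = realized_bend_deg(conf)
    se = 8.0 / math.sqrt(150)
    assert bends.mean() == pytest.approx(52.0, abs=4 * se)


def test_zero_bend_zero_jitter_collinear(tar):
    conf, _ = gen_rna_conformers(tar, bend_deg=0.0, jitter_deg=0.0,
                                 n_conformers=2, seed=0)
    bends = realized_bend_deg(conf)
    np.testing.assert_allclose(bends, 0.0, atol=1e-8)


def test_conformer_length_mismatch_rejected(tar):
    with pytest.raises(ValueError):
        gen_rna_conformers(tar, stem_lengths=(10, 10), loop_length=6)


def test_turbidity_amplitude_zero_is_flat_baseline():
    curve, _ = gen_turbidity(amplitude=0.0, baseline=0.05, noise_sd=0.0)
    np.testing.assert_allclose(curve.a340, 0.05)


def test_turbidity_parameter_validation():
    with pytest.raises(ValueError):
        gen_turbidity(width=0.0)
    with pytest.raises(ValueError):
        gen_turbidity(peak_ratio=-1.0)


def test_pre_oracle_agrees_with_vectorized_implementation(rng):
    """Dual implementations agree to 1e-10 relative on random ensembles."""
    ens = Ensemble(rng.normal(scale=12.0, size=(25, 18, 3)))
    fast = pre_profile(ens, label_site=7)
    oracle, _ = gen_pre_truth(ens, label_site=7)
    np.testing.assert_allclose(fast.values, oracle.values, rtol=1e-10)


def test_pre_all_ones_when_gamma_zero(rng):
    ens = Ensemble(rng.normal(scale=12.0, size=(5, 10, 3)))
    prof, _ = gen_pre_truth(ens, label_site=5, params={"K": 0.0})
    assert np.all(prof.values[np.arange(10) != 4] == pytest.approx(1.0))


def test_pre_basin_two_sided_for_interior_label(rng):
    """An end label attenuates one flank; an interior label both flanks.

    Uses a near-extended chain (spacing 3.8 A plus small jitter) so the
    site-label distance grows with sequence separation and the attenuation
    basin is local, as for a chain with excluded volume.
    """
    n = 40
    base = np.zeros((30, n, 3))
    base[:, :, 0] = 3.8 * np.arange(n)
    base += rng.normal(scale=0.5, size=base.shape)
    end = pre_profile(Ensemble(base), label_site=1).values
    mid = pre_profile(Ensemble(base), label_site=20).values
    assert end[2] < 0.5 < end[n - 1]
    assert mid[16] < 0.5 and mid[22] < 0.5   # both flanks of the label
    assert mid[0] > 0.9 and mid[n - 1] > 0.9
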