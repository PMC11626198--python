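"""Ensemble observables: Rg/KDE, distance maps, AFRC null, PRE, scattering,
secondary structure and chemical-shift perturbations."""

import math

import numpy as np
import pandas as pd
import pytest

from fuzzbind.observables import (Ensemble, ScatteringCurve, ShiftTable,
                                  afrc_reference, csp, debye_scattering,
                                  guinier_fit, helicity_profile,
                                  kratky_dimensionless, mean_distance_map,
                                  normalized_distance_map, pre_profile,
                                  rg_distribution, ssp_from_shifts)
from fuzzbind.synthetic import gen_chain_ensemble


# ---------------------------------------------------------------- Rg / KDE
def test_two_site_rg_is_half_distance():
    ens = Ensemble(np.array([[[0., 0, 0], [4.0, 0, 0]]]))
    assert rg_distribution(ens).rg[0] == pytest.approx(2.0)


def test_three_collinear_sites_rg():
    d = 3.0
    ens = Ensemble(np.array([[[0., 0, 0], [d, 0, 0], [2 * d, 0, 0]]]))
    assert rg_distribution(ens).rg[0] == pytest.approx(d * math.sqrt(2.0 / 3.0))


def test_kde_density_integrates_to_one():
    ens, _ = gen_chain_ensemble(30, n_frames=150, seed=9)
    dist = rg_distribution(ens)
    integral = np.trapezoid(dist.density, dist.grid)
    assert integral == pytest.approx(1.0, abs=1e-3)


def test_single_site_rg_warns_and_is_zero():
    ens = Ensemble(np.zeros((3, 1, 3)))
    with pytest.warns(UserWarning):
        assert np.all(rg_distribution(ens).rg == 0.0)


# ------------------------------------------------------------ distance maps
def test_single_frame_distance_map_is_pairwise_matrix(rng):
    xyz = rng.normal(size=(1, 6, 3))
    m = mean_distance_map(Ensemble(xyz))
    expect = np.linalg.norm(xyz[0][:, None] - xyz[0][None, :], axis=2)
    np.testing.assert_allclose(m, expect)
    np.testing.assert_allclose(m, m.T)
    assert np.all(np.diag(m) == 0)


def test_distance_map_matches_bruteforce_toy(rng):
    xyz = rng.normal(size=(3, 5, 3))
    m = mean_distance_map(Ensemble(xyz))
    for i in range(5):
        for j in range(5):
            acc = sum(np.sqrt(((xyz[f, i] - xyz[f, j]) ** 2).sum())
                      for f in range(3)) / 3
            assert m[i, j] == pytest.approx(acc)


# -------------------------------------------------------------------- AFRC
def test_afrc_rg_for_68_residue_chain():
    ref = afrc_reference(68)
    assert ref.rg == pytest.approx(20.8, abs=1.0)


def test_afrc_sqrt_scaling():
    ref = afrc_reference(100)
    for k in (2, 5, 10):
        assert ref.mean_distance(4 * k) == pytest.approx(2 * ref.mean_distance(k))


def test_afrc_two_residue_contract():
    ref = afrc_reference(2)
    # closed forms: rms Rg = b/2 and rms 1-separation distance = b
    assert ref.rg == pytest.approx(ref.rms_distance(1) / 2)


def test_afrc_rejects_single_residue():
    with pytest.raises(ValueError):
        afrc_reference(1)


def test_normalized_map_self_consistency():
    ref = afrc_reference(40)
    ens = ref.sample(600, seed=3)
    nd = normalized_distance_map(mean_distance_map(ens), ref)
    off = nd[~np.isnan(nd)]
    assert np.mean(off) == pytest.approx(1.0, abs=0.05)


def test_normalized_map_linear_in_scale():
    ref = afrc_reference(20)
    ens = ref.sample(100, seed=4)
    m = mean_distance_map(ens)
    nd = normalized_distance_map(m, ref)
    nd_half = normalized_distance_map(0.5 * m, ref)
    np.testing.assert_allclose(nd_half, 0.5 * nd)


def test_normalized_map_detects_prefactor_ratio():
    # Gaussian chain with bond length b vs reference with prefactor b'
    b, bprime = 5.0, 6.18
    ens, _ = gen_chain_ensemble(30, bond_b=b, n_frames=800, seed=5,
                                bond_model="gaussian")
    ref = afrc_reference(30, prefactor=bprime)
    nd = normalized_distance_map(mean_distance_map(ens), ref)
    assert np.nanmean(nd) == pytest.approx(b / bprime, rel=0.03)


def test_normalized_map_size_mismatch():
    with pytest.raises(ValueError):
        normalized_distance_map(np.zeros((5, 5)), afrc_reference(6))


# --------------------------------------------------------------------- PRE
def test_pre_limits():
    # residue at the label -> 0; residue very far -> ~1
    c = np.zeros((1, 3, 3))
    c[0, 1, 0] = 1e4
    c[0, 2, 0] = 8.0
    p = pre_profile(Ensemble(c), label_site=1)
    assert p.values[0] == 0.0
    assert p.values[1] == pytest.approx(1.0, abs=1e-6)
    assert 0.0 < p.values[2] < 1.0


def test_pre_single_frame_formula_oracle():
    """Fixed 20 A distance: direct evaluation of the two formulas."""
    c = np.zeros((1, 2, 3)); c[0, 1, 0] = 20.0
    p = pre_profile(Ensemble(c), label_site=1)
    gamma2 = 1.23e16 * 4e-9 * 20.0 ** -6
    expect = 10.0 * math.exp(-gamma2 * 10e-3) / (10.0 + gamma2)
    assert p.values[1] == pytest.approx(expect, rel=1e-12)


def test_pre_ratios_bounded(rng):
    ens = Ensemble(rng.normal(scale=15.0, size=(40, 25, 3)))
    p = pre_profile(ens, label_site=13)
    assert np.all((p.values >= 0) & (p.values <= 1))


# ---------------------------------------------------------------- helicity
def test_full_helix_interior_is_one():
    ens, _ = gen_chain_ensemble(20, helix_region=(1, 20, 1.0),
                                n_frames=10, seed=2)
    h = helicity_profile(ens)
    assert np.all(h.values[1:-1] == 1.0)


def test_extended_chain_has_zero_helicity():
    ens, _ = gen_chain_ensemble(20, n_frames=10, seed=2)
    assert np.all(helicity_profile(ens).values == 0.0)


def test_half_helical_frames_give_half_fraction():
    ens, _ = gen_chain_ensemble(30, helix_region=(8, 22, 0.5),
                                n_frames=600, seed=3)
    h = helicity_profile(ens)
    interior = h.values[9:20]
    assert np.mean(interior) == pytest.approx(0.5, abs=0.06)
    outside = np.concatenate([h.values[:6], h.values[23:]])
    assert np.all(outside == 0.0)


def test_helicity_requires_dihedrals():
    with pytest.raises(ValueError):
        helicity_profile(Ensemble(np.zeros((2, 5, 3))))


# --------------------------------------------------------------------- SSP
def _shift_table(residues, dca, dcb):
    rows = []
    for r, a, b in zip(residues, dca, dcb):
        rows.append({"residue": r, "nucleus": "CA", "shift_ppm": 50.0 + a,
                     "rc_shift_ppm": 50.0})
        rows.append({"residue": r, "nucleus": "CB", "shift_ppm": 30.0 + b,
                     "rc_shift_ppm": 30.0})
    return ShiftTable(pd.DataFrame(rows))


def test_ssp_zero_at_random_coil():
    t = _shift_table(range(1, 11), [0.0] * 10, [0.0] * 10)
    assert np.allclose(ssp_from_shifts(t).values, 0.0)


def test_ssp_full_helix_scaling():
    t = _shift_table(range(1, 11), [2.8] * 10, [0.0] * 10)
    assert np.allclose(ssp_from_shifts(t).values, 1.0)


def test_ssp_antisymmetric_under_sign_flip():
    rng = np.random.default_rng(0)
    dca = rng.normal(scale=1.0, size=12)
    dcb = rng.normal(scale=0.5, size=12)
    plus = ssp_from_shifts(_shift_table(range(1, 13), dca, dcb)).values
    minus = ssp_from_shifts(_shift_table(range(1, 13), -dca, -dcb)).values
    np.testing.assert_allclose(minus, -plus)


def test_ssp_requires_reference():
    t = ShiftTable(pd.DataFrame([{"residue": 1, "nucleus": "CA",
                                  "shift_ppm": 50.0}]))
    with pytest.raises(ValueError):
        ssp_from_shifts(t)


# --------------------------------------------------------------------- CSP
def _one_residue_table(shifts: dict):
    rows = [{"residue": 5, "nucleus": nu, "shift_ppm": v}
            for nu, v in shifts.items()]
    return ShiftTable(pd.DataFrame(rows))


def test_csp_identical_tables_zero():
    a = _one_residue_table({"H": 8.0, "N": 118.0})
    comb, _mx = csp(a, a)
    assert comb.values[0] == pytest.approx(0.0)


def test_csp_weighted_combination_example():
    a = _one_residue_table({"H": 8.00, "N": 118.00})
    b = _one_residue_table({"H": 8.10, "N": 118.50})
    comb, _ = csp(a, b)
    expect = math.sqrt((0.10 ** 2 + (0.154 * 0.50) ** 2) / 2)
    assert comb.values[0] == pytest.approx(expect, rel=1e-9)
    assert expect == pytest.approx(0.0893, abs=2e-4)


def test_csp_max_carbon_variant():
    a = _one_residue_table({"CA": 52.0, "CB": 31.0, "H": 8.0})
    b = _one_residue_table({"CA": 52.4, "CB": 31.1, "H": 8.0})
    _, mx = csp(a, b)
    assert mx.values[0] == pytest.approx(0.4)


def test_csp_disjoint_tables_rejected():
    a = _one_residue_table({"H": 8.0})
    b = ShiftTable(pd.DataFrame([{"residue": 9, "nucleus": "H",
                                  "shift_ppm": 8.0}]))
    with pytest.raises(ValueError):
        csp(a, b)


# --------------------------------------------------------------- scattering
def test_single_site_scattering_constant():
    ens = Ensemble(np.zeros((2, 1, 3)))
    q = np.linspace(0, 0.5, 20)
    c = debye_scattering(ens, q)
    np.testing.assert_allclose(c.intensity, 1.0)


def test_two_site_closed_form():
    d = 7.0
    ens = Ensemble(np.array([[[0., 0, 0], [d, 0, 0]]]))
    q = np.linspace(0.0, 0.6, 50)
    c = debye_scattering(ens, q)
    expect = 2 * (1 + np.sinc(q * d / np.pi))
    np.testing.assert_allclose(c.intensity, expect, rtol=1e-12)


def test_coherent_limit_n_squared(rng):
    n = 9
    ens = Ensemble(rng.normal(size=(4, n, 3)))
    c = debye_scattering(ens, np.array([0.0, 0.01]))
    assert c.intensity[0] == pytest.approx(n * n)


def test_guinier_exact_recovery():
    rg0 = 24.5
    q = np.linspace(0.002, 0.2, 250)
    curve = ScatteringCurve(q, 37.0 * np.exp(-q ** 2 * rg0 ** 2 / 3.0))
    out = guinier_fit(curve)
    assert out["rg"] == pytest.approx(rg0, rel=1e-6)
    assert out["i0"] == pytest.approx(37.0, rel=1e-6)
    assert out["q_max"] * out["rg"] <= 1.3 + 1e-9


def test_guinier_scale_invariance():
    q = np.linspace(0.002, 0.2, 250)
    i = np.exp(-q ** 2 * 20.0 ** 2 / 3.0)
    rg1 = guinier_fit(ScatteringCurve(q, i))["rg"]
    rg2 = guinier_fit(ScatteringCurve(q, 123.0 * i))["rg"]
    assert rg1 == pytest.approx(rg2, rel=1e-12)


def test_guinier_rejects_rising_curve():
    q = np.linspace(0.01, 0.2, 50)
    with pytest.raises(ValueError):
        guinier_fit(ScatteringCurve(q, np.exp(+q ** 2)))


def test_debye_guinier_consistent_with_coordinate_rg(rng):
    """Guinier Rg of a computed curve matches the direct coordinate Rg."""
    xyz = rng.normal(scale=8.0, size=(1, 40, 3))
    ens = Ensemble(xyz)
    rg_coord = rg_distribution(ens).rg[0]
    q = np.linspace(0.001, 0.08, 200)
    out = guinier_fit(debye_scattering(ens, q))
    assert out["rg"] == pytest.approx(rg_coord, rel=0.02)


def test_kratky_peak_of_ideal_guinier_curve():
    rg0 = 21.0
    q = np.linspace(0.0005, 0.25, 4000)
    curve = ScatteringCurve(q, np.exp(-q ** 2 * rg0 ** 2 / 3.0))
    x, y = kratky_dimensionless(curve, rg0)
    assert y[0] == pytest.approx(0.0, abs=1e-3)
    assert x[np.argmax(y)] == pytest.approx(math.sqrt(3.0), abs=0.01)
    assert y.max() == pytest.approx(3.0 / math.e, abs=1e-3)


def test_kratky_intensity_scale_invariant():
    q = np.linspace(0.001, 0.2, 100)
    i = np.exp(-q ** 2 * 100.0)
    _, y1 = kratky_dimensionless(ScatteringCurve(q, i), 17.0)
    _, y2 = kratky_dimensionless(ScatteringCurve(q, 55.0 * i), 17.0)
    np.testing.assert_allclose(y1, y2)
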