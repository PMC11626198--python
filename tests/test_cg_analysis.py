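"""Bound-state classification, apparent K_D, contact maps, Rg by state."""

import numpy as np
import pytest

from fuzzbind.cg import (SimConfig, Trajectory, apparent_kd, classify_bound,
                         contact_frequency, pool_contact_maps,
                         relative_affinity, rg_by_state, SaturationWarning)
from fuzzbind.cg.analysis import BindingStateSeries


def toy_trajectory(frames, box=25.0, n_a=3, sigmas=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    chain_index = np.array([0] * n_a + [1] * (n - n_a))
    return Trajectory(frames=frames, box_edge=box, chain_index=chain_index,
                      chain_ids=["protein", "rna"], stride=1,
                      config={"bound_min_contacts": 1},
                      sigmas=sigmas if sigmas is not None else np.full(n, 0.5))


def test_separated_chains_never_bound():
    f = np.zeros((5, 4, 3))
    f[:, 2:, 0] = 10.0  # second chain 10 nm away in a 25 nm box
    states = classify_bound(toy_trajectory(f, n_a=2), cutoff=1.0)
    assert states.bound_fraction == 0.0
    assert np.all(states.min_distance > 1.0)


def test_half_bound_toy_enumeration():
    f = np.zeros((4, 2, 3))
    f[0, 1, 0] = 0.5   # bound
    f[1, 1, 0] = 9.0   # unbound
    f[2, 1, 0] = 0.7   # bound
    f[3, 1, 0] = 9.0   # unbound
    states = classify_bound(toy_trajectory(f, n_a=1), cutoff=1.0)
    assert states.bound_fraction == pytest.approx(0.5)


def test_classification_matches_bruteforce_oracle(rng):
    """Random toy trajectory vs an exhaustive O(N^2) pure-python recount."""
    box = 6.0
    f = rng.uniform(0, box, size=(12, 7, 3))
    traj = toy_trajectory(f, box=box, n_a=4)
    cutoff, min_contacts = 1.3, 2
    states = classify_bound(traj, cutoff=cutoff, min_contacts=min_contacts)
    for t in range(12):
        n_contacts = 0
        best = np.inf
        for i in range(4):
            for j in range(4, 7):
                d = f[t, i] - f[t, j]
                d -= box * np.round(d / box)
                r = np.sqrt((d ** 2).sum())
                best = min(best, r)
                n_contacts += r < cutoff
        assert states.bound[t] == (n_contacts >= min_contacts)
        assert states.min_distance[t] == pytest.approx(best)


def test_minimum_image_convention_used():
    box = 10.0
    f = np.zeros((1, 2, 3))
    f[0, 1, 0] = 9.8   # only 0.2 nm away through the boundary
    states = classify_bound(toy_trajectory(f, box=box, n_a=1), cutoff=0.5)
    assert states.bound_fraction == 1.0


def test_apparent_kd_closed_form():
    s = BindingStateSeries(np.array([True, False]), np.array([0.1, 5.0]), 1.0, 1)
    kd = apparent_kd(s, SimConfig(box_edge=25.0))
    # f_b = 0.5 in a (25 nm)^3 box: 0.5 / (V N_A) ~ 53.1 uM
    assert kd == pytest.approx(53.1e-6, rel=0.01)


def test_apparent_kd_saturation_warns():
    s = BindingStateSeries(np.ones(4, bool), np.zeros(4), 1.0, 1)
    with pytest.warns(SaturationWarning):
        assert apparent_kd(s, SimConfig()) == 0.0
    s0 = BindingStateSeries(np.zeros(4, bool), np.ones(4), 1.0, 1)
    with pytest.warns(SaturationWarning):
        assert np.isinf(apparent_kd(s0, SimConfig()))


def test_relative_affinity_symmetry():
    assert relative_affinity(1e-6, 3.5e-6) == pytest.approx(3.5)
    assert relative_affinity(2e-6, 2e-6) == pytest.approx(1.0)


def test_contact_frequency_static_geometry_is_binary():
    f = np.zeros((6, 4, 3))
    f[:, 2, 0] = 0.4   # always in contact with bead 0
    f[:, 3, 0] = 5.0   # never
    cmap = contact_frequency(toy_trajectory(f, n_a=2), cutoff=1.0)
    assert set(np.unique(cmap.matrix)) <= {0.0, 1.0}
    assert cmap.matrix.shape == (2, 2)


def test_contact_frequency_matches_bruteforce(rng):
    box = 5.0
    f = rng.uniform(0, box, size=(20, 6, 3))
    traj = toy_trajectory(f, box=box, n_a=3)
    cmap = contact_frequency(traj, cutoff=1.0)
    for i in range(3):
        for j in range(3):
            cnt = 0
            for t in range(20):
                d = f[t, i] - f[t, 3 + j]
                d -= box * np.round(d / box)
                cnt += np.sqrt((d ** 2).sum()) < 1.0
            assert cmap.matrix[i, j] == pytest.approx(cnt / 20)
    assert np.all((cmap.matrix >= 0) & (cmap.matrix <= 1))


def test_bound_only_restriction_never_lowers_frequencies(rng):
    box = 8.0
    f = rng.uniform(0, box, size=(30, 5, 3))
    traj = toy_trajectory(f, box=box, n_a=2)
    states = classify_bound(traj, cutoff=1.5, min_contacts=1)
    assert 0 < states.bound_fraction < 1
    all_frames = contact_frequency(traj, cutoff=1.5)
    bound_only = contact_frequency(traj, cutoff=1.5, bound_only=True,
                                   states=states)
    assert np.all(bound_only.matrix >= all_frames.matrix - 1e-12)


def test_pooled_maps_mean_and_sd():
    m1 = contact_frequency(toy_trajectory(np.zeros((2, 3, 3)), n_a=1), cutoff=1.0)
    f2 = np.zeros((2, 3, 3)); f2[:, 1:, 0] = 9.0
    m2 = contact_frequency(toy_trajectory(f2, n_a=1), cutoff=1.0)
    pooled = pool_contact_maps([m1, m2])
    assert pooled.matrix == pytest.approx(0.5 * (m1.matrix + m2.matrix))
    assert np.all(pooled.conformer_sd >= 0)


def test_rg_by_state_two_bead_chain():
    d = 1.4
    f = np.zeros((4, 3, 3))
    f[:, 1, 0] = d        # chain "protein" = beads 0-1
    f[:2, 2, 0] = 0.5     # bound in first two frames
    f[2:, 2, 0] = 8.0
    traj = toy_trajectory(f, box=20.0, n_a=2)
    states = classify_bound(traj, cutoff=1.0)
    out = rg_by_state(traj, states, "protein")
    assert np.allclose(out["rg"], d / 2)
    assert out["n_bound"] + out["n_unbound"] == 4
    assert out["n_bound"] == 2


def test_rg_by_state_requires_alignment():
    f = np.zeros((3, 3, 3))
    traj = toy_trajectory(f, n_a=2)
    bad = BindingStateSeries(np.zeros(5, bool), np.zeros(5), 1.0, 1)
    with pytest.raises(ValueError):
        rg_by_state(traj, bad, "protein")


def test_single_chain_trajectory_rejected():
    f = np.zeros((3, 4, 3))
    traj = Trajectory(frames=f, box_edge=10.0,
                      chain_index=np.zeros(4, dtype=int),
                      chain_ids=["protein"], stride=1, config={},
                      sigmas=np.full(4, 0.5))
    with pytest.raises(ValueError):
        classify_bound(traj, cutoff=1.0)
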