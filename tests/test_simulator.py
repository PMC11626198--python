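"""Topology building and the Langevin engine's statistical-mechanics contracts."""

import math

import numpy as np
import pytest

from fuzzbind.cg import (ConformerSet, IntegrationError, SimConfig,
                         Trajectory, build_topology, run_simulation,
                         simulate_conformers)
from fuzzbind.cg.forcefield import BeadType, ForceField
from fuzzbind.cg.topology import TopologyError
from fuzzbind.sequences import BioSequence
from fuzzbind.synthetic import gen_rna_conformers


def test_topology_bead_and_bond_counts(serf, forcefield):
    top = build_topology(protein=serf, table=forcefield)
    assert top.n_beads == 68
    assert len(top.bonds) == 67
    nterm = BioSequence("serf_1_34", "protein", serf.residues[:34])
    top34 = build_topology(protein=nterm, table=forcefield)
    assert top34.n_beads == 34
    assert len(top34.bonds) == 33


def test_topology_rejects_empty_sequence(forcefield):
    with pytest.raises(ValueError):
        BioSequence("e", "protein", "")


def test_topology_rejects_conformer_size_mismatch(tar, forcefield):
    bad = ConformerSet(np.zeros((2, 10, 3)), units="angstrom", sequence=tar)
    with pytest.raises(TopologyError):
        build_topology(rna=bad, table=forcefield)


def test_missing_bead_type_raises():
    tiny = ForceField({"A": BeadType("A", "protein", 71.0, 0.0, 0.5, 0.3, 2, 1)})
    with pytest.raises(KeyError):
        build_topology(protein=BioSequence("p", "protein", "AG"), table=tiny)


def test_rigid_chain_topology(tar, forcefield):
    conf, _ = gen_rna_conformers(tar, n_conformers=4, seed=1)
    top = build_topology(rna=conf, table=forcefield)
    assert top.chains[0].flexible is False
    assert top.chains[0].conformers.shape == (4, 29, 3)
    assert len(top.bonds) == 0  # rigid chain gets no springs


@pytest.fixture(scope="module")
def short_chain_config():
    return SimConfig(box_edge=8.0, nonbonded_cutoff=2.5, n_steps=20_000,
                     save_every=500, seed=7, friction=0.5)


def test_seeded_runs_bitwise_identical(forcefield, short_chain_config):
    top = build_topology(protein=BioSequence("p", "protein", "MARGNQKDNAKK"),
                         table=forcefield)
    t1 = run_simulation(top, short_chain_config)
    t2 = run_simulation(top, short_chain_config)
    assert np.array_equal(t1.frames, t2.frames)
    t3 = run_simulation(top, SimConfig(**{**short_chain_config.__dict__,
                                          "seed": 8}))
    assert not np.array_equal(t1.frames, t3.frames)


def test_frame_count_contract(forcefield, short_chain_config):
    top = build_topology(protein=BioSequence("p", "protein", "MARGNQ"),
                         table=forcefield)
    traj = run_simulation(top, short_chain_config)
    assert traj.n_frames == short_chain_config.n_steps // short_chain_config.save_every


def test_langevin_temperature_matches_setpoint(forcefield):
    """Equipartition: kinetic temperature within 2% over >= 1e5 steps."""
    top = build_topology(protein=BioSequence("p", "protein", "MARGNQKDNA"),
                         table=forcefield)
    cfg = SimConfig(box_edge=8.0, nonbonded_cutoff=2.5, n_steps=120_000,
                    save_every=100, seed=11, friction=1.0)
    traj = run_simulation(top, cfg)
    assert traj.temperatures.mean() == pytest.approx(300.0, rel=0.02)


def test_harmonic_bond_length_statistics(forcefield, short_chain_config):
    """Mean bond length ~ r0 within the thermal broadening of the spring."""
    top = build_topology(protein=BioSequence("p", "protein", "GGGGGGGG"),
                        table=forcefield)
    traj = run_simulation(top, short_chain_config)
    bonds = np.linalg.norm(np.diff(traj.frames, axis=1), axis=2)
    r0 = top.bond_r0[0]
    # <r> = r0 + 2 kT/(k r0) to first order for r-space Boltzmann statistics
    kt = 8.31446e-3 * 300.0
    expected = r0 + 2.0 * kt / (top.bond_k[0] * r0)
    assert bonds.mean() == pytest.approx(expected, rel=0.02)


def test_ideal_chain_rg_scaling():
    """With nonbonded terms off, Rg follows the ideal-chain closed form."""
    n = 20
    neutral = ForceField({"G": BeadType("G", "protein", 57.0, 0.0, 0.45, 0.0, 2, 1)})
    top = build_topology(protein=BioSequence("p", "protein", "G" * n),
                         table=neutral)
    cfg = SimConfig(box_edge=10.0, nonbonded_cutoff=2.0, n_steps=200_000,
                    save_every=200, seed=3, friction=1.0)
    traj = run_simulation(top, cfg)
    rel = traj.frames - traj.frames[:, :1, :]
    rel -= cfg.box_edge * np.round(rel / cfg.box_edge)
    cent = rel.mean(axis=1, keepdims=True)
    rg = np.sqrt(((rel - cent) ** 2).sum(axis=2).mean(axis=1))
    b2 = top.bond_r0[0] ** 2 + 3 * cfg.kt / top.bond_k[0]
    expected = math.sqrt(b2 * (n * n - 1.0) / (6.0 * n))
    assert rg.mean() == pytest.approx(expected, rel=0.10)


def test_numerical_blowup_reported_with_step(forcefield):
    top = build_topology(protein=BioSequence("p", "protein", "KKKKKK"),
                         table=forcefield)
    cfg = SimConfig(box_edge=8.0, nonbonded_cutoff=2.5, n_steps=2_000,
                    save_every=10, seed=1, timestep=1e6)  # absurd timestep
    with pytest.raises(IntegrationError, match="step"):
        run_simulation(top, cfg)


def test_rigid_body_geometry_preserved(serf, tar, forcefield):
    conf, _ = gen_rna_conformers(tar, n_conformers=2, seed=2)
    top = build_topology(protein=BioSequence("p", "protein", serf.residues[:10]),
                         rna=conf, table=forcefield)
    cfg = SimConfig(box_edge=10.0, nonbonded_cutoff=2.5, n_steps=5_000,
                    save_every=500, seed=4)
    traj = run_simulation(top, cfg, conformer_index=1)
    sl = traj.chain_slice("rna")
    d_first = np.linalg.norm(
        traj.frames[0, sl][:, None] - traj.frames[0, sl][None, :], axis=2)
    d_last = np.linalg.norm(
        traj.frames[-1, sl][:, None] - traj.frames[-1, sl][None, :], axis=2)
    np.testing.assert_allclose(d_first, d_last, atol=1e-8)
    # and it matches conformer 1's internal geometry (nm)
    ref = conf.in_nm().coords[1]
    d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
    np.testing.assert_allclose(d_first, d_ref, atol=1e-8)


def test_pooled_conformer_runs_are_distinct_and_reproducible(tar, forcefield):
    conf, _ = gen_rna_conformers(tar, n_conformers=2, seed=3)
    top = build_topology(protein=BioSequence("p", "protein", "MKKRRG"),
                         rna=conf, table=forcefield)
    cfg = SimConfig(box_edge=10.0, nonbonded_cutoff=2.5, n_steps=4_000,
                    save_every=500, seed=9)
    runs = simulate_conformers(top, cfg)
    assert [t.conformer_index for t in runs] == [0, 1]
    runs2 = simulate_conformers(top, cfg)
    for a, b in zip(runs, runs2):
        assert np.array_equal(a.frames, b.frames)


def test_trajectory_save_load_roundtrip(tmp_path, forcefield, short_chain_config):
    top = build_topology(protein=BioSequence("p", "protein", "MARGNQ"),
                         table=forcefield)
    traj = run_simulation(top, short_chain_config)
    base = tmp_path / "traj"
    traj.save(base)
    back = Trajectory.load(base)
    np.testing.assert_array_equal(back.frames, traj.frames)
    assert back.chain_ids == traj.chain_ids
    assert back.stride == traj.stride
    assert back.config["seed"] == short_chain_config.seed


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(box_edge=5.0, nonbonded_cutoff=3.0)
    with pytest.raises(ValueError):
        SimConfig(n_steps=10, save_every=100)
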