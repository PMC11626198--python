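"""Bound-state classification, apparent K_D, contact maps and Rg-by-state.

With exactly one molecule of each species in a periodic box of volume V, the
bound fraction f_b of saved frames gives a mass-action apparent dissociation
constant

    K_D,app = (1 - f_b)^2 / (f_b * V * N_A)

and the relative affinity of two RNAs for the same protein is the ratio of
their K_D values, which is volume-independent when the boxes match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import Trajectory, SimConfig

__all__ = ["BindingStateSeries", "ContactMap", "classify_bound",
           "apparent_kd", "relative_affinity", "contact_frequency",
           "pool_contact_maps", "rg_by_state", "SaturationWarning"]

_AVOGADRO = 6.02214076e23


class SaturationWarning(UserWarning):
    """Bound fraction is 0 or 1; no finite K_D estimate."""


@dataclass
class BindingStateSeries:
    bound: np.ndarray          # (n_frames,) bool
    min_distance: np.ndarray   # (n_frames,) nm, min interchain bead distance
    cutoff: float
    min_contacts: int

    @property
    def bound_fraction(self) -> float:
        return float(np.mean(self.bound))

    @property
    def n_frames(self) -> int:
        return len(self.bound)


@dataclass
class ContactMap:
    """Protein-residue x RNA-nucleotide contact frequencies in [0, 1]."""

    matrix: np.ndarray                    # (n_protein, n_rna)
    cutoff: float
    marginal_kind: str = "mean"           # how marginals collapse the other axis
    conformer_mean: np.ndarray | None = None
    conformer_sd: np.ndarray | None = None

    @property
    def per_residue(self) -> np.ndarray:
        op = np.mean if self.marginal_kind == "mean" else np.max
        return op(self.matrix, axis=1)

    @property
    def per_nucleotide(self) -> np.ndarray:
        op = np.mean if self.marginal_kind == "mean" else np.max
        return op(self.matrix, axis=0)


def _two_chain_slices(traj: Trajectory) -> tuple[slice, slice]:
    ids = np.unique(traj.chain_index)
    if len(ids) != 2:
        raise ValueError(f"need exactly two chains, trajectory has {len(ids)}")
    a = np.flatnonzero(traj.chain_index == ids[0])
    b = np.flatnonzero(traj.chain_index == ids[1])
    return (slice(int(a[0]), int(a[-1]) + 1), slice(int(b[0]), int(b[-1]) + 1))


def _interchain_distances(traj: Trajectory) -> np.ndarray:
    """(n_frames, nA, nB) minimum-image interchain distances in nm."""
    sa, sb = _two_chain_slices(traj)
    d = traj.frames[:, sa, None, :] - traj.frames[:, None, sb, :]
    box = traj.box_edge
    d -= box * np.round(d / box)
    return np.sqrt((d ** 2).sum(axis=-1))


def classify_bound(traj: Trajectory, cutoff: float | None = None,
                   min_contacts: int | None = None) -> BindingStateSeries:
    """Per-frame bound flag: >= min_contacts interchain bead pairs within cutoff.

    Default cutoff is 1.2 x the mean pair contact distance (mean over bead
    pairs of (sigma_i + sigma_j)/2) when the trajectory carries bead sizes.
    """
    cfg = traj.config or {}
    if min_contacts is None:
        min_contacts = int(cfg.get("bound_min_contacts", 1))
    if cutoff is None:
        cutoff = cfg.get("bound_cutoff")
    if cutoff is None:
        if traj.sigmas is None:
            raise ValueError("no cutoff given and trajectory has no bead sizes")
        sa, sb = _two_chain_slices(traj)
        pair_sigma = 0.5 * (traj.sigmas[sa][:, None] + traj.sigmas[sb][None, :])
        cutoff = 1.2 * float(pair_sigma.mean())
    dist = _interchain_distances(traj)
    n_contacts = (dist < cutoff).sum(axis=(1, 2))
    return BindingStateSeries(
        bound=n_contacts >= min_contacts,
        min_distance=dist.min(axis=(1, 2)),
        cutoff=float(cutoff), min_contacts=int(min_contacts))


def apparent_kd(states: BindingStateSeries, config: SimConfig | dict) -> float:
    """Apparent K_D (molar) from the bound fraction of a one-pair box.

    Returns nan with a :class:`SaturationWarning` when f_b is 0 or 1.
    """
    box = config.box_edge if isinstance(config, SimConfig) else config["box_edge"]
    fb = states.bound_fraction
    if fb <= 0.0 or fb >= 1.0:
        warnings.warn(
            f"bound fraction {fb:g} is saturated; no finite K_D estimate",
            SaturationWarning)
        return 0.0 if fb >= 1.0 else np.inf
    volume_l = box ** 3 * 1e-24  # nm^3 -> L
    return (1.0 - fb) ** 2 / (fb * volume_l * _AVOGADRO)


def relative_affinity(kd_rna1: float, kd_rna2: float) -> float:
    """Affinity of RNA1 relative to RNA2 = K_D(2) / K_D(1); > 1 means RNA1 binds
    tighter. Volume-independent when box sizes match."""
    return kd_rna2 / kd_rna1


def contact_frequency(traj: Trajectory, cutoff: float = 1.0,
                      bound_only: bool = False,
                      states: BindingStateSeries | None = None) -> ContactMap:
    """Fraction of frames in which each protein-RNA bead pair is within cutoff (nm)."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    dist = _interchain_distances(traj)
    if bound_only:
        if states is None:
            states = classify_bound(traj)
        mask = states.bound
        if not mask.any():
            raise ValueError("no bound frames to restrict to")
        dist = dist[mask]
    return ContactMap(matrix=(dist < cutoff).mean(axis=0), cutoff=cutoff)


def pool_contact_maps(maps: list[ContactMap]) -> ContactMap:
    """Average per-conformer maps; SD across conformers reported alongside."""
    if not maps:
        raise ValueError("no maps to pool")
    stack = np.stack([m.matrix for m in maps])
    return ContactMap(matrix=stack.mean(axis=0), cutoff=maps[0].cutoff,
                      conformer_mean=stack.mean(axis=0),
                      conformer_sd=stack.std(axis=0, ddof=0))


def rg_by_state(traj: Trajectory, states: BindingStateSeries,
                chain: str) -> dict:
    """Per-frame radius of gyration of one chain, split by bound flag.

    The chain is reassembled across periodic boundaries relative to its first
    bead before computing Rg (bonded chains never span half the box).
    """
    if states.n_frames != traj.n_frames:
        raise ValueError("states not aligned to trajectory frames")
    sl = traj.chain_slice(chain)
    coords = traj.frames[:, sl, :].copy()
    box = traj.box_edge
    rel = coords - coords[:, :1, :]
    rel -= box * np.round(rel / box)
    cent = rel.mean(axis=1, keepdims=True)
    rg = np.sqrt(((rel - cent) ** 2).sum(axis=2).mean(axis=1))
    bound = states.bound
    return {
        "rg": rg,
        "bound": rg[bound],
        "unbound": rg[~bound],
        "mean_bound": float(rg[bound].mean()) if bound.any() else np.nan,
        "mean_unbound": float(rg[~bound].mean()) if (~bound).any() else np.nan,
        "n_bound": int(bound.sum()),
        "n_unbound": int((~bound).sum()),
    }
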