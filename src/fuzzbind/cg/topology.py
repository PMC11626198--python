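"""Bead-resolution topology for one- or two-molecule simulations.

A chain is either fully flexible (consecutive beads joined by harmonic bonds)
or a single rigid group supplied as one or more conformer coordinate sets; a
folded RNA hairpin is represented by its NMR-style conformers, each simulated
as a rigid body, while a disordered protein or homopolymer RNA is a flexible
bead-spring chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..sequences import BioSequence
from .forcefield import ForceField, BeadType

__all__ = ["ConformerSet", "Chain", "Topology", "build_topology",
           "BOND_K_DEFAULT", "BOND_R0_PROTEIN", "BOND_R0_RNA"]

BOND_K_DEFAULT = 8000.0   # kJ/mol/nm^2
BOND_R0_PROTEIN = 0.381   # nm, Calpha-Calpha virtual bond
BOND_R0_RNA = 0.50        # nm, P-P virtual bond


class TopologyError(ValueError):
    pass


@dataclass
class ConformerSet:
    """One coordinate per residue for each of several conformers.

    coords has shape (n_conformers, n_sites, 3). ``units`` records whether the
    coordinates are in angstrom (as read from PDB) or nm (simulation units).
    """

    coords: np.ndarray
    units: str = "angstrom"
    sequence: BioSequence | None = None
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_conformers, n_sites, 3)")
        if self.units not in ("angstrom", "nm"):
            raise ValueError("units must be 'angstrom' or 'nm'")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]

    def in_nm(self) -> "ConformerSet":
        if self.units == "nm":
            return self
        return ConformerSet(self.coords * 0.1, "nm", self.sequence, self.source)


@dataclass
class Chain:
    chain_id: str
    kind: str                      # "protein" | "rna"
    letters: str
    bead_types: list[BeadType]
    flexible: bool = True
    conformers: np.ndarray | None = None   # (n_conf, n_beads, 3) in nm, rigid only

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)


@dataclass
class Topology:
    """Chains plus the harmonic-bond list, with flat per-bead parameter arrays."""

    chains: list[Chain]
    bonds: np.ndarray = field(default=None)     # (n_bonds, 2) global indices
    bond_k: np.ndarray = field(default=None)
    bond_r0: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.bonds is None:
            self.bonds = np.zeros((0, 2), dtype=np.int64)
            self.bond_k = np.zeros(0)
            self.bond_r0 = np.zeros(0)

    # -- flat per-bead views -------------------------------------------------
    @property
    def n_beads(self) -> int:
        return sum(c.n_beads for c in self.chains)

    def chain_index(self) -> np.ndarray:
        return np.concatenate([
            np.full(c.n_beads, i, dtype=np.int64) for i, c in enumerate(self.chains)
        ])

    def chain_slice(self, chain_id: str) -> slice:
        start = 0
        for c in self.chains:
            if c.chain_id == chain_id:
                return slice(start, start + c.n_beads)
            start += c.n_beads
        raise KeyError(f"no chain {chain_id!r} in topology")

    def bead_array(self, attr: str) -> np.ndarray:
        return np.array([getattr(bt, attr) for c in self.chains for bt in c.bead_types])

    def rigid_chains(self) -> list[int]:
        return [i for i, c in enumerate(self.chains) if not c.flexible]


def _make_chain(seq: BioSequence, table: ForceField, chain_id: str,
                conformers: ConformerSet | None = None) -> Chain:
    if len(seq) == 0:
        raise TopologyError("empty sequence")
    beads = [table.bead_for(c, seq.kind) for c in seq.residues]
    if conformers is None:
        return Chain(chain_id, seq.kind, seq.residues, beads, flexible=True)
    conf = conformers.in_nm()
    if conf.n_sites != len(seq):
        raise TopologyError(
            f"conformer sets have {conf.n_sites} sites but sequence "
            f"{seq.identifier!r} has {len(seq)} residues"
        )
    return Chain(chain_id, seq.kind, seq.residues, beads, flexible=False,
                 conformers=conf.coords.copy())


def build_topology(protein: BioSequence | None = None,
                   rna: BioSequence | ConformerSet | None = None,
                   table: ForceField | None = None,
                   bond_k: float = BOND_K_DEFAULT) -> Topology:
    """Assemble a one- or two-chain topology.

    ``rna`` may be a BioSequence (flexible polymer, e.g. (rU)29) or a
    ConformerSet carrying its sequence (rigid body per conformer, e.g. a
    structured hairpin). Flexible chains receive consecutive harmonic bonds
    with kind-specific rest lengths.
    """
    if table is None:
        from .forcefield import load_forcefield
        table = load_forcefield()
    chains: list[Chain] = []
    if protein is not None:
        chains.append(_make_chain(protein, table, "protein"))
    if rna is not None:
        if isinstance(rna, ConformerSet):
            if rna.sequence is None:
                raise TopologyError("ConformerSet must carry its RNA sequence")
            chains.append(_make_chain(rna.sequence, table, "rna", conformers=rna))
        else:
            chains.append(_make_chain(rna, table, "rna"))
    if not chains:
        raise TopologyError("topology needs at least one chain")

    bonds, ks, r0s = [], [], []
    offset = 0
    for c in chains:
        if c.flexible:
            r0 = BOND_R0_PROTEIN if c.kind == "protein" else BOND_R0_RNA
            for i in range(c.n_beads - 1):
                bonds.append((offset + i, offset + i + 1))
                ks.append(bond_k)
                r0s.append(r0)
        offset += c.n_beads
    top = Topology(chains=chains)
    top.bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    top.bond_k = np.array(ks)
    top.bond_r0 = np.array(r0s)
    return top
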