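"""Readers/writers for the standard formats the pipeline touches.

FASTA and multi-MODEL PDB parsing go through Biopython; coordinates are read
in angstrom (PDB convention) and converted to nm only at the simulation
boundary. Every writer records units and provenance in its output.
"""

from __future__ import annotations

import datetime
import hashlib
import sys
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from .sequences import BioSequence, PROTEIN_ALPHABET
from .cg.topology import ConformerSet
from .observables import Ensemble

__all__ = ["read_fasta", "write_fasta", "read_conformers_pdb",
           "ensemble_from_pdb", "ensemble_from_trajectory", "read_config",
           "RunLog", "file_digest"]


class FastaParseError(ValueError):
    pass


def _infer_kind(letters: str) -> str:
    s = set(letters.upper())
    if s <= set("ACGU"):
        return "rna"
    if s <= set("ACGT") or s <= set("ACGTU"):
        return "rna"
    if s <= PROTEIN_ALPHABET:
        return "protein"
    raise FastaParseError(f"cannot infer alphabet for letters {sorted(s)}")


def read_fasta(path, kind: str | None = None) -> list[BioSequence]:
    """Read sequences from FASTA; ``kind`` declares protein/rna (else inferred
    per record). For RNA, T is normalized to U."""
    path = Path(path)
    # fail early with a line number on grossly malformed input
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path.name}:{ln}: expected '>' header before sequence data")
            break
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        letters = str(rec.seq).upper().replace(" ", "")
        k = kind or _infer_kind(letters)
        if k == "rna":
            letters = letters.replace("T", "U")
        out.append(BioSequence(identifier=rec.id, kind=k, residues=letters))
    return out


def write_fasta(seqs: list[BioSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.identifier}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i:i + 60] + "\n")


_RNA_THREE_TO_ONE = {"A": "A", "C": "C", "G": "G", "U": "U",
                     "RA": "A", "RC": "C", "RG": "G", "RU": "U"}


def read_conformers_pdb(path, site_atom: str = "P",
                        fallback_atom: str = "C1'",
                        log=None) -> ConformerSet:
    """One coordinate per residue per MODEL from the named atom.

    Missing ``site_atom`` falls back to ``fallback_atom`` (typical at the 5'
    terminus, which has no phosphate); a residue with neither raises an error
    naming the residue and model. Coordinates in angstrom.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("conf", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no MODEL records in {path}")
    coords = []
    letters = []
    for m_i, model in enumerate(models, start=1):
        sites = []
        letters_m = []
        for chain in model:
            for res in chain:
                if res.id[0] != " ":
                    continue  # skip heteroatoms/water
                if site_atom in res:
                    sites.append(res[site_atom].coord)
                elif fallback_atom in res:
                    if log is not None:
                        log.write(f"model {m_i} residue {res.id[1]}: "
                                  f"{site_atom} absent, using {fallback_atom}")
                    sites.append(res[fallback_atom].coord)
                else:
                    raise ValueError(
                        f"residue {res.get_resname().strip()}{res.id[1]} in "
                        f"model {m_i} has neither {site_atom} nor {fallback_atom}")
                if m_i == 1:
                    name = res.get_resname().strip().upper()
                    letters_m.append(_RNA_THREE_TO_ONE.get(name, "N"))
        coords.append(np.array(sites, dtype=float))
        if m_i == 1:
            letters = letters_m
    n_sites = {len(c) for c in coords}
    if len(n_sites) != 1:
        raise ValueError(f"models have inconsistent site counts {sorted(n_sites)}")
    seq = None
    if letters and all(l in "ACGU" for l in letters):
        seq = BioSequence(Path(path).stem, "rna", "".join(letters))
    return ConformerSet(coords=np.stack(coords), units="angstrom",
                        sequence=seq, source=str(path))


def ensemble_from_pdb(path, site_atom: str = "CA") -> Ensemble:
    """Protein conformational ensemble from a multi-MODEL PDB (one site = CA)."""
    conf = read_conformers_pdb(path, site_atom=site_atom, fallback_atom=site_atom)
    return Ensemble(coords=conf.coords)


def ensemble_from_trajectory(traj, chain: str) -> Ensemble:
    """Ensemble (angstrom) of one chain of a CG trajectory (nm), reassembled
    across periodic boundaries."""
    sl = traj.chain_slice(chain)
    coords = traj.frames[:, sl, :].copy()
    rel = coords - coords[:, :1, :]
    rel -= traj.box_edge * np.round(rel / traj.box_edge)
    return Ensemble(coords=rel * 10.0)   # nm -> angstrom


def read_config(path) -> dict:
    """Parse a TOML run configuration."""
    import tomllib
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


class RunLog:
    """Line-oriented run log with ISO timestamps (seed, versions, digests)."""

    def __init__(self, path):
        self.path = Path(path)
        self.fh = open(self.path, "a")

    def write(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.fh.write(f"{stamp} {msg}\n")
        self.fh.flush()

    def header(self, seed=None, inputs=()):
        import fuzzbind
        self.write(f"fuzzbind {fuzzbind.__version__} python {sys.version.split()[0]}")
        if seed is not None:
            self.write(f"seed {seed}")
        for p in inputs:
            self.write(f"input {p} sha256:{file_digest(p)}")

    def close(self):
        self.fh.close()
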