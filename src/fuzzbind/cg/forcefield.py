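"""Residue-level pair energetics: Wang-Frenkel short range + Debye-Hueckel.

Each amino acid or ribonucleotide is a single bead with a type-specific size
(sigma), short-range interaction strength (epsilon) and charge. The
short-range term is the Wang-Frenkel potential

    U_wf(r) = eps * alpha * [(sigma/r)^(2 mu) - 1] * [(Rc/r)^(2 mu) - 1]^(2 nu)

with cutoff Rc = 3 sigma, where alpha is fixed so that the well depth is
exactly -eps; the potential and its derivative vanish smoothly at Rc, so no
shifting is required. Screened electrostatics use the Debye-Hueckel form

    U_el(r) = q_i q_j * l_B * k_B T * exp(-r / lambda_D) / r

with the Bjerrum length l_B set by temperature and dielectric and the Debye
length lambda_D set by ionic strength. Inside the simulation engine the
electrostatic term is truncated at the nonbonded cutoff and shifted to be
continuous there.

The bundled parameter table is a synthetic, package-authored parameterization
in the style of residue-resolution IDP/RNA force fields (see the table header);
any table with the same columns can be substituted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BeadType",
    "ForceField",
    "load_forcefield",
    "bjerrum_length_nm",
    "debye_length_nm",
    "wang_frenkel_energy",
    "debye_huckel_energy",
    "pair_energy",
]

KB_KJMOL = 8.31446e-3  # kJ/mol/K
# e^2 / (4 pi eps0 kB) in nm*K: Bjerrum length = this / (eps_r * T)
_BJERRUM_NUM_NM_K = 16679.5
_AVOGADRO = 6.02214076e23


def bjerrum_length_nm(temperature: float, dielectric: float) -> float:
    """Bjerrum length (nm) at the given temperature (K) and relative permittivity."""
    return _BJERRUM_NUM_NM_K / (dielectric * temperature)


def debye_length_nm(ionic_strength_mM: float, temperature: float = 300.0,
                    dielectric: float = 80.0) -> float:
    """Debye screening length (nm) for a 1:1 electrolyte.

    kappa^2 = 8 pi l_B n with n the salt number density; 150 mM at 300 K in
    water gives ~0.79 nm.
    """
    if ionic_strength_mM <= 0:
        return np.inf
    lb = bjerrum_length_nm(temperature, dielectric)
    n_per_nm3 = ionic_strength_mM * 1e-3 * _AVOGADRO / 1e24
    kappa2 = 8.0 * np.pi * lb * n_per_nm3
    return 1.0 / np.sqrt(kappa2)


@dataclass(frozen=True)
class BeadType:
    """Parameters of one residue/nucleotide bead type."""

    code: str
    kind: str
    mass: float          # g/mol
    charge: float        # elementary charges
    sigma: float         # nm
    epsilon: float       # kJ/mol
    mu: float            # Wang-Frenkel range exponent
    nu: float            # Wang-Frenkel shape exponent

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0 for bead {self.code!r}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0 for bead {self.code!r}")


class ForceField:
    """A loaded bead-parameter table with pair-combination rules."""

    def __init__(self, beads: dict[str, BeadType], source: str = "<memory>"):
        if not beads:
            raise ValueError("empty force-field table")
        self.beads = beads
        self.source = source

    def __getitem__(self, code: str) -> BeadType:
        try:
            return self.beads[code]
        except KeyError:
            raise KeyError(
                f"bead type {code!r} missing from force-field table {self.source}"
            ) from None

    def bead_for(self, letter: str, kind: str) -> BeadType:
        """Look up the bead for a sequence letter. RNA letters are stored
        lower-case in the table to keep the alphabets disjoint."""
        code = letter.lower() if kind == "rna" else letter.upper()
        bt = self[code]
        if bt.kind != kind:
            raise KeyError(f"bead {code!r} is not of kind {kind!r}")
        return bt


def load_forcefield(path=None) -> ForceField:
    """Read a bead-parameter TSV (code, kind, mass, charge, sigma, epsilon, mu, nu)."""
    if path is None:
        ref = importlib.resources.files("fuzzbind.data") / "cg_forcefield_synthetic.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_forcefield(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    beads = {}
    for row in df.itertuples(index=False):
        beads[str(row.code)] = BeadType(
            code=str(row.code), kind=str(row.kind), mass=float(row.mass_gmol),
            charge=float(row.charge_e), sigma=float(row.sigma_nm),
            epsilon=float(row.epsilon_kJmol), mu=float(row.mu), nu=float(row.nu),
        )
    return ForceField(beads, source=str(path))


def _wf_alpha(rc_over_sigma: float, mu: float, nu: float) -> float:
    x = rc_over_sigma ** (2.0 * mu)
    return (2.0 * nu * x) * ((1.0 + 2.0 * nu) / (2.0 * nu * (x - 1.0))) ** (2.0 * nu + 1.0)


def combine(a: BeadType, b: BeadType) -> tuple[float, float, float, float]:
    """Lorentz/Berthelot-style pair parameters (sigma, epsilon, mu, nu)."""
    return (
        0.5 * (a.sigma + b.sigma),
        float(np.sqrt(a.epsilon * b.epsilon)),
        0.5 * (a.mu + b.mu),
        0.5 * (a.nu + b.nu),
    )


def wang_frenkel_energy(r, sigma: float, epsilon: float, mu: float = 2.0,
                        nu: float = 1.0, rc_factor: float = 3.0):
    """Wang-Frenkel energy (kJ/mol); exactly 0 at and beyond rc = rc_factor*sigma."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be > 0")
    rc = rc_factor * sigma
    alpha = _wf_alpha(rc_factor, mu, nu)
    with np.errstate(over="ignore"):
        u = epsilon * alpha * ((sigma / r) ** (2 * mu) - 1.0) * \
            ((rc / r) ** (2 * mu) - 1.0) ** (2 * nu)
    return np.where(r < rc, u, 0.0)


def debye_huckel_energy(r, q1: float, q2: float, temperature: float = 300.0,
                        dielectric: float = 80.0, ionic_strength_mM: float = 150.0):
    """Unshifted screened-Coulomb energy (kJ/mol) between point charges (e)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be > 0")
    lb = bjerrum_length_nm(temperature, dielectric)
    ld = debye_length_nm(ionic_strength_mM, temperature, dielectric)
    kt = KB_KJMOL * temperature
    return q1 * q2 * lb * kt * np.exp(-r / ld) / r


def pair_energy(a: BeadType, b: BeadType, r, config=None):
    """Total pair energy (kJ/mol): Wang-Frenkel + shifted Debye-Hueckel.

    ``config`` supplies temperature, dielectric, ionic strength and the
    electrostatic cutoff; defaults (300 K, 80, 150 mM, 3 nm) are used when
    None. The electrostatic term is shifted so the total is continuous at the
    cutoff; the Wang-Frenkel term already vanishes smoothly at 3*sigma_ij.
    """
    from .simulate import SimConfig  # local import to avoid cycle

    cfg = config if config is not None else SimConfig()
    sigma, eps, mu, nu = combine(a, b)
    u = wang_frenkel_energy(r, sigma, eps, mu, nu)
    if a.charge != 0.0 and b.charge != 0.0:
        rc = cfg.nonbonded_cutoff
        uel = debye_huckel_energy(r, a.charge, b.charge, cfg.temperature,
                                  cfg.dielectric, cfg.ionic_strength)
        shift = debye_huckel_energy(rc, a.charge, b.charge, cfg.temperature,
                                    cfg.dielectric, cfg.ionic_strength)
        r_arr = np.asarray(r, dtype=float)
        u = u + np.where(r_arr < rc, uel - shift, 0.0)
    return u if np.ndim(r) else float(u)
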