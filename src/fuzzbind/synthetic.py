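"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of (parameters, seed) and returns its
dataset together with a TruthRecord capturing the generating parameters, so
closure tests (does the fitter recover the generating K_D? does the helicity
profile recover the generating helix fraction?) can be run without any
external data. The default parameters are the study conditions: titrations
mimic a micromolar-affinity protein-RNA anisotropy experiment, chain
ensembles mimic a disordered ~70-residue protein with a partially populated
helix, RNA conformers mimic a two-helix hairpin with an interhelical bend,
and turbidity curves peak at the charge-matched protein:RNA ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .binding import TitrationSeries, anisotropy_model
from .observables import Ensemble, ObservableProfile, PRE_DEFAULTS
from .phase import TurbidityCurve
from .sequences import BioSequence
from .cg.topology import ConformerSet

__all__ = ["TruthRecord", "gen_titration", "gen_chain_ensemble",
           "gen_rna_conformers", "gen_turbidity", "gen_pre_truth"]

# stream tags: one RNG stream per generator under a shared master seed
_STREAMS = {"titration": 1, "chain_ensemble": 2, "rna_conformers": 3,
            "turbidity": 4, "pre_truth": 5}


def _rng(generator: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[generator], int(seed)])


@dataclass
class TruthRecord:
    """Generating parameters of a synthetic dataset; re-running the named
    generator with these parameters and seed reproduces the data exactly."""

    generator: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps({"generator": self.generator, "seed": self.seed,
                        "params": self.params}, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(generator=d["generator"], params=d["params"], seed=d["seed"])


def gen_titration(kd: float, r_free: float = 0.08, r_bound: float = 0.20,
                  probe: float = 10e-9, n_points: int = 16,
                  x_max: float = 20e-6, x_min: float | None = None,
                  noise_sd: float = 0.002, replicates: int = 3,
                  seed: int = 0) -> tuple[TitrationSeries, TruthRecord]:
    """Synthetic 1:1 anisotropy titration with i.i.d. Gaussian noise.

    A log-spaced titrant grid (default spanning 10 nM probe conditions up to
    20 uM titrant) is evaluated with the exact-depletion 1:1 model; each of
    ``replicates`` technical replicates gets independent noise and the series
    reports the replicate mean and (ddof=1) SD per point.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if n_points < 5:
        raise ValueError("need at least 5 points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if x_min is None:
        x_min = x_max / 2000.0
    rng = _rng("titration", seed)
    x = np.geomspace(x_min, x_max, n_points)
    truth = anisotropy_model(probe, x, {"kd": kd, "r_free": r_free,
                                        "r_bound": r_bound}, "one_to_one")
    reps = truth[None, :] + noise_sd * rng.standard_normal((replicates, n_points))
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if replicates > 1 else None
    series = TitrationSeries(probe_total=probe, titrant_totals=x,
                             anisotropy=mean, replicate_sd=sd)
    rec = TruthRecord("titration", {"kd": kd, "r_free": r_free,
                                    "r_bound": r_bound, "probe": probe,
                                    "n_points": n_points, "x_max": x_max,
                                    "x_min": x_min, "noise_sd": noise_sd,
                                    "replicates": replicates}, seed)
    return series, rec


# ideal alpha-helix Calpha trace parameters
_HELIX_RADIUS = 2.30     # A
_HELIX_RISE = 1.50       # A per residue
_HELIX_TWIST = 100.0     # degrees per residue
_HELIX_PHI_PSI = (-63.0, -42.0)


def _helix_trace(n: int) -> np.ndarray:
    t = np.arange(n) * math.radians(_HELIX_TWIST)
    return np.column_stack([_HELIX_RADIUS * np.cos(t),
                            _HELIX_RADIUS * np.sin(t),
                            _HELIX_RISE * np.arange(n)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2*(y*y + z*z), 2*(x*y - w*z), 2*(x*z + w*y)],
        [2*(x*y + w*z), 1 - 2*(x*x + z*z), 2*(y*z - w*x)],
        [2*(x*z - w*y), 2*(y*z + w*x), 1 - 2*(x*x + y*y)]])


def gen_chain_ensemble(n_res: int, bond_b: float = 3.8,
                       helix_region: tuple[int, int, float] | None = None,
                       compaction: float = 1.0, n_frames: int = 200,
                       seed: int = 0, bond_model: str = "fixed",
                       ) -> tuple[Ensemble, TruthRecord]:
    """Polymer-chain ensemble with optional helical segment and dihedrals.

    The backbone is a freely jointed chain with fixed bond length ``bond_b``
    (angstrom); with ``bond_model='gaussian'`` bond vectors are drawn from an
    isotropic Gaussian of the same mean-square length, which reproduces
    ideal-chain (random-coil null model) statistics exactly at every
    separation. ``helix_region=(start, end, fraction)`` (1-based, inclusive)
    replaces that segment with an ideal alpha-helix trace in the stated
    fraction of frames; the dihedral table is consistent with the geometry
    (alpha-basin values in helical frames, extended-basin values elsewhere,
    NaN at chain termini). All coordinates are finally scaled by
    ``compaction``.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    if bond_model not in ("fixed", "gaussian"):
        raise ValueError("bond_model must be 'fixed' or 'gaussian'")
    start = end = None
    fraction = 0.0
    if helix_region is not None:
        start, end, fraction = helix_region
        if not (1 <= start < end <= n_res):
            raise ValueError(f"helix region ({start}, {end}) outside chain 1..{n_res}")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("helix fraction must be in [0, 1]")
    rng = _rng("chain_ensemble", seed)
    coords = np.zeros((n_frames, n_res, 3))
    dihedrals = np.full((n_frames, n_res, 2), np.nan)
    helical_frames = rng.random(n_frames) < fraction if helix_region else \
        np.zeros(n_frames, dtype=bool)

    for f in range(n_frames):
        # coil dihedrals in the extended/PPII basin, clearly outside alpha
        dihedrals[f, 1:-1, 0] = rng.uniform(-160.0, -110.0, n_res - 2)
        dihedrals[f, 1:-1, 1] = rng.uniform(110.0, 170.0, n_res - 2)
        xyz = np.zeros((n_res, 3))
        if helical_frames[f]:
            s, e = start - 1, end  # 0-based [s, e)
            helix = _helix_trace(e - s) @ _random_rotation(rng).T
            for i in range(1, n_res):
                if s < i < e:
                    xyz[i] = xyz[s] + (helix[i - s] - helix[0])
                else:
                    v = rng.normal(size=3)
                    if bond_model == "fixed":
                        v *= bond_b / np.linalg.norm(v)
                    else:
                        v *= bond_b / math.sqrt(3.0)
                    xyz[i] = xyz[i - 1] + v
            lo = max(s, 1)
            hi = min(e, n_res - 1)
            dihedrals[f, lo:hi, 0] = _HELIX_PHI_PSI[0]
            dihedrals[f, lo:hi, 1] = _HELIX_PHI_PSI[1]
        else:
            if bond_model == "fixed":
                v = rng.normal(size=(n_res - 1, 3))
                v *= bond_b / np.linalg.norm(v, axis=1, keepdims=True)
            else:
                v = rng.normal(scale=bond_b / math.sqrt(3.0),
                               size=(n_res - 1, 3))
            xyz[1:] = np.cumsum(v, axis=0)
        coords[f] = xyz * compaction

    ens = Ensemble(coords=coords, dihedrals=dihedrals)
    rec = TruthRecord("chain_ensemble",
                      {"n_res": n_res, "bond_b": bond_b,
                       "helix_region": list(helix_region) if helix_region else None,
                       "compaction": compaction, "n_frames": n_frames,
                       "bond_model": bond_model}, seed)
    return ens, rec


# toy A-form-like helical rod: one site per nucleotide
_RNA_RADIUS = 9.0     # A
_RNA_RISE = 2.8       # A per nucleotide
_RNA_TWIST = 32.7     # degrees per nucleotide


def _rna_helix(n: int) -> np.ndarray:
    t = np.arange(n) * math.radians(_RNA_TWIST)
    return np.column_stack([_RNA_RADIUS * np.cos(t),
                            _RNA_RADIUS * np.sin(t),
                            _RNA_RISE * np.arange(n)])


def _roty(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), 0, math.sin(a)], [0, 1, 0],
                     [-math.sin(a), 0, math.cos(a)]])


def gen_rna_conformers(seq: BioSequence, stem_lengths: tuple[int, int] = (12, 11),
                       loop_length: int = 6, bend_deg: float = 52.0,
                       n_conformers: int = 15, jitter_deg: float = 8.0,
                       seed: int = 0) -> tuple[ConformerSet, TruthRecord]:
    """Toy helix-junction-helix conformer set for a hairpin RNA.

    Nucleotides are placed one site each on two ideal helical rods whose axes
    meet at ``bend_deg`` (the interhelical angle), bridged by a circular-arc
    loop; conformers differ by seeded Gaussian angular jitter about the bend.
    Coordinates in angstrom, with the sequence attached for topology building.
    """
    s1, s2 = stem_lengths
    if s1 + s2 + loop_length != len(seq):
        raise ValueError(
            f"stems {s1}+{s2} plus loop {loop_length} != sequence length {len(seq)}")
    if s1 < 2 or s2 < 2:
        raise ValueError("each stem needs at least 2 nucleotides")
    rng = _rng("rna_conformers", seed)
    confs = np.zeros((n_conformers, len(seq), 3))
    for c in range(n_conformers):
        d_bend = bend_deg + (rng.normal(0.0, jitter_deg) if jitter_deg > 0 else 0.0)
        h1 = _rna_helix(s1)
        # loop: circular arc in the bend plane from stem1 end
        arc_r = max(_RNA_RISE * (loop_length + 1) / math.pi, 4.0)
        ang = np.linspace(0, math.pi, loop_length + 2)[1:-1]
        arc = np.column_stack([arc_r * np.sin(ang), np.zeros(loop_length),
                               arc_r * (1 - np.cos(ang)) / 2.0])
        loop = h1[-1] + arc + np.array([0, 0, _RNA_RISE])
        # stem2: helical rod with axis rotated by (180 - bend) from +z, i.e.
        # heading back down so the two axis directions subtend the bend angle
        h2 = _rna_helix(s2) @ _roty(180.0 - d_bend).T
        anchor = loop[-1] if loop_length else h1[-1]
        h2 = h2 - h2[0] + anchor + np.array([_RNA_RISE, 0, 0])
        confs[c] = np.vstack([h1, loop, h2])
    conf = ConformerSet(coords=confs, units="angstrom", sequence=seq,
                        source=f"gen_rna_conformers(seed={seed})")
    rec = TruthRecord("rna_conformers",
                      {"sequence": seq.residues, "stem_lengths": [s1, s2],
                       "loop_length": loop_length, "bend_deg": bend_deg,
                       "n_conformers": n_conformers, "jitter_deg": jitter_deg},
                      seed)
    return conf, rec


def realized_bend_deg(conformers: ConformerSet, stem_lengths=(12, 11),
                      loop_length: int = 6) -> np.ndarray:
    """Angle (degrees) between the two stem axis directions per conformer,
    with each axis taken as the principal direction of its stem sites, signed
    along the 5'->3' site order."""
    s1, s2 = stem_lengths
    out = np.empty(conformers.n_conformers)
    for c in range(conformers.n_conformers):
        xyz = conformers.coords[c]
        def axis(block):
            # for an ideal helix the cross product of successive bond vectors
            # is a constant axial part plus a transverse part rotating with
            # the twist; regressing on [1, cos, sin] of the twist phase
            # isolates the axial part exactly even for partial turns
            bonds = np.diff(block, axis=0)
            cp = np.cross(bonds[:-1], bonds[1:])
            ph = np.arange(len(cp)) * math.radians(_RNA_TWIST)
            X = np.column_stack([np.ones_like(ph), np.cos(ph), np.sin(ph)])
            beta, *_ = np.linalg.lstsq(X, cp, rcond=None)
            a = beta[0] / np.linalg.norm(beta[0])
            if np.dot(a, block[-1] - block[0]) < 0:
                a = -a
            return a
        a1 = axis(xyz[:s1])
        a2 = axis(xyz[s1 + loop_length:])
        # interhelical angle: deviation from antiparallel stacking of the
        # 5'->3' axis directions
        cosang = np.clip(np.dot(a1, -a2), -1.0, 1.0)
        out[c] = math.degrees(math.acos(cosang))
    return out


def gen_turbidity(peak_ratio: float = 29.0 / 12.0, width: float = 0.35,
                  amplitude: float = 1.0, baseline: float = 0.02,
                  noise_sd: float = 0.02, n_points: int = 16,
                  x_max: float = 6.0, plateau: bool = False,
                  seed: int = 0) -> tuple[TurbidityCurve, TruthRecord]:
    """Synthetic turbidity titration peaking at ``peak_ratio``.

    The noiseless profile is a log-normal bump
    baseline + amplitude * exp(-(ln(x / peak))^2 / (2 width^2)); with
    ``plateau=True`` the signal saturates at the peak value beyond the peak.
    Defaults peak at the charge-matched ratio for a +12 protein and a -29 RNA.
    """
    if peak_ratio <= 0:
        raise ValueError("peak_ratio must be > 0")
    if width <= 0:
        raise ValueError("width must be > 0")
    rng = _rng("turbidity", seed)
    x = np.linspace(x_max / n_points, x_max, n_points)
    bump = amplitude * np.exp(-np.log(x / peak_ratio) ** 2 / (2 * width ** 2))
    if plateau:
        bump = np.where(x >= peak_ratio, amplitude, bump)
    y = np.clip(baseline + bump + noise_sd * rng.standard_normal(n_points), 0, None)
    curve = TurbidityCurve(x=x, a340=y,
                           sd=np.full(n_points, noise_sd) if noise_sd > 0 else None)
    rec = TruthRecord("turbidity", {"peak_ratio": peak_ratio, "width": width,
                                    "amplitude": amplitude, "baseline": baseline,
                                    "noise_sd": noise_sd, "n_points": n_points,
                                    "x_max": x_max, "plateau": plateau}, seed)
    return curve, rec


def gen_pre_truth(ens: Ensemble, label_site: int,
                  params: dict | None = None) -> tuple[ObservableProfile, TruthRecord]:
    """Straight-line independent evaluation of the PRE formulas.

    Deliberately shares no code with the observables module: explicit loops
    over frames and residues, used as the test oracle for the vectorized
    implementation.
    """
    p = {**PRE_DEFAULTS, **(params or {})}
    labels = list(ens.labels)
    if label_site not in labels:
        raise ValueError(f"label site {label_site} not in ensemble")
    li = labels.index(label_site)
    w = ens.frame_weights()
    values = []
    for i in range(ens.n_sites):
        if i == li:
            values.append(0.0)
            continue
        acc = 0.0
        for f in range(ens.n_frames):
            dx = ens.coords[f, i, 0] - ens.coords[f, li, 0]
            dy = ens.coords[f, i, 1] - ens.coords[f, li, 1]
            dz = ens.coords[f, i, 2] - ens.coords[f, li, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            acc += w[f] * r ** (-6.0)
        gamma2 = p["K"] * p["tau_c"] * acc
        ratio = p["r2_intrinsic"] * math.exp(-gamma2 * p["t_delay"]) \
            / (p["r2_intrinsic"] + gamma2)
        values.append(ratio)
    prof = ObservableProfile(ens.labels, np.array(values),
                             name="pre_intensity_ratio_oracle",
                             units="dimensionless")
    rec = TruthRecord("pre_truth", {"label_site": label_site, "params": p}, 0)
    return prof, rec
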