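"""Langevin dynamics of one or two coarse-grained molecules in a periodic box.

The integrator is BAOAB splitting of underdamped Langevin dynamics. Flexible
chains are bead-spring polymers; a rigid chain (e.g. a folded RNA conformer)
moves as a rigid body: its center of mass follows translational Langevin
dynamics and its orientation evolves by the Euler equations in the principal
frame with an Ornstein-Uhlenbeck thermostat on the body-frame angular
velocity. Internal units: nm, ps, g/mol, kJ/mol (1 kJ/mol = 1 g nm^2/ps^2/mol).

For a rigid chain supplied as several conformers, the default protocol is to
simulate each conformer in a separate run and pool the statistics
(``simulate_conformers``); an alternative seeded conformer-swap Monte Carlo
mode exchanges the rigid coordinates between chunks of dynamics with a
Metropolis test after least-squares superposition onto the current pose.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .forcefield import (KB_KJMOL, bjerrum_length_nm, debye_length_nm,
                         _wf_alpha)
from .topology import Topology

__all__ = ["SimConfig", "Trajectory", "IntegrationError", "run_simulation",
           "simulate_conformers", "potential_energy"]


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Simulation conditions; defaults are standard for this force-field class
    and chosen so that binding and unbinding events both occur for weakly
    associating pairs."""

    box_edge: float = 25.0            # nm
    temperature: float = 300.0        # K
    ionic_strength: float = 150.0     # mM, sets the Debye length
    dielectric: float = 80.0
    timestep: float = 0.01            # ps (10 fs)
    friction: float = 0.01            # 1/ps
    n_steps: int = 100_000
    save_every: int = 1_000
    seed: int = 0
    nonbonded_cutoff: float = 3.0     # nm (electrostatics truncation)
    bound_cutoff: float | None = None  # nm; None -> 1.2 x mean pair sigma
    bound_min_contacts: int = 1
    equilibration_fraction: float = 0.1
    conformer_mode: str = "pooled"    # "pooled" | "swap"
    swap_every: int = 5_000           # steps between swap attempts

    def __post_init__(self):
        if self.box_edge <= 2 * self.nonbonded_cutoff:
            raise ValueError("box_edge must exceed twice the nonbonded cutoff")
        if not (self.n_steps >= self.save_every >= 1):
            raise ValueError("need n_steps >= save_every >= 1")
        if self.conformer_mode not in ("pooled", "swap"):
            raise ValueError("conformer_mode must be 'pooled' or 'swap'")

    @property
    def kt(self) -> float:
        return KB_KJMOL * self.temperature


@dataclass
class Trajectory:
    """Saved frames of a run, with enough metadata to analyze it standalone."""

    frames: np.ndarray                 # (n_frames, n_beads, 3) nm
    box_edge: float
    chain_index: np.ndarray            # (n_beads,) chain id per bead
    chain_ids: list[str]
    stride: int
    config: dict = field(default_factory=dict)
    sigmas: np.ndarray | None = None   # (n_beads,) nm
    charges: np.ndarray | None = None
    temperatures: np.ndarray | None = None
    conformer_index: int | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def chain_slice(self, chain_id: str) -> slice:
        i = self.chain_ids.index(chain_id)
        idx = np.flatnonzero(self.chain_index == i)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def save(self, path) -> None:
        """Write as .npz plus a JSON sidecar (units nm, stride, config echo)."""
        path = str(path)
        np.savez_compressed(
            path if path.endswith(".npz") else path + ".npz",
            frames=self.frames, chain_index=self.chain_index,
            sigmas=self.sigmas if self.sigmas is not None else np.zeros(0),
            charges=self.charges if self.charges is not None else np.zeros(0),
            temperatures=(self.temperatures if self.temperatures is not None
                          else np.zeros(0)),
        )
        side = {
            "units": "nm", "box_edge": self.box_edge, "stride": self.stride,
            "chain_ids": self.chain_ids, "config": self.config,
            "conformer_index": self.conformer_index,
        }
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump(side, fh, indent=1)

    @classmethod
    def load(cls, path) -> "Trajectory":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        dat = np.load(base + ".npz")
        with open(base + ".json") as fh:
            side = json.load(fh)
        def opt(name):
            arr = dat[name]
            return arr if arr.size else None
        return cls(frames=dat["frames"], box_edge=side["box_edge"],
                   chain_index=dat["chain_index"], chain_ids=side["chain_ids"],
                   stride=side["stride"], config=side["config"],
                   sigmas=opt("sigmas"), charges=opt("charges"),
                   temperatures=opt("temperatures"),
                   conformer_index=side["conformer_index"])


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _quat_mul(a, b, out):
    out[0] = a[0]*b[0] - a[1]*b[1] - a[2]*b[2] - a[3]*b[3]
    out[1] = a[0]*b[1] + a[1]*b[0] + a[2]*b[3] - a[3]*b[2]
    out[2] = a[0]*b[2] - a[1]*b[3] + a[2]*b[0] + a[3]*b[1]
    out[3] = a[0]*b[3] + a[1]*b[2] - a[2]*b[1] + a[3]*b[0]


@njit(cache=True)
def _quat_to_mat(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1 - 2*(y*y + z*z); R[0, 1] = 2*(x*y - w*z); R[0, 2] = 2*(x*z + w*y)
    R[1, 0] = 2*(x*y + w*z); R[1, 1] = 1 - 2*(x*x + z*z); R[1, 2] = 2*(y*z - w*x)
    R[2, 0] = 2*(x*z - w*y); R[2, 1] = 2*(y*z + w*x); R[2, 2] = 1 - 2*(x*x + y*y)


@njit(cache=True)
def _rotvec_quat(v, out):
    angle = math.sqrt(v[0]*v[0] + v[1]*v[1] + v[2]*v[2])
    out[0] = math.cos(0.5 * angle)
    if angle > 1e-14:
        s = math.sin(0.5 * angle) / angle
        out[1] = v[0]*s; out[2] = v[1]*s; out[3] = v[2]*s
    else:
        out[1] = 0.5*v[0]; out[2] = 0.5*v[1]; out[3] = 0.5*v[2]


@njit(cache=True)
def _reconstruct(pos, nrig, r_start, r_end, bodyc, quat, com):
    R = np.empty((3, 3))
    for b in range(nrig):
        _quat_to_mat(quat[b], R)
        for i in range(r_start[b], r_end[b]):
            for k in range(3):
                pos[i, k] = (com[b, k] + R[k, 0]*bodyc[i, 0]
                             + R[k, 1]*bodyc[i, 1] + R[k, 2]*bodyc[i, 2])


@njit(cache=True)
def _forces(pos, box, excl, eps2d, sig2d, mu2d, nu2d, alpha2d, qqpref,
            inv_ld, el_rc, bonds, bond_k, bond_r0, f):
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0; f[i, 1] = 0.0; f[i, 2] = 0.0
    energy = 0.0
    el_rc2 = el_rc * el_rc
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = pos[i, 0] - pos[j, 0]; dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box); dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r2 = dx*dx + dy*dy + dz*dz
            if r2 < 1e-24:   # exactly coincident beads: clamp, the
                r2 = 1e-24   # finiteness check reports the blow-up
            sig = sig2d[i, j]
            wf_rc = 3.0 * sig
            fr = 0.0  # force magnitude / r
            if r2 < wf_rc * wf_rc:
                mu = mu2d[i, j]; nu = nu2d[i, j]
                ea = eps2d[i, j] * alpha2d[i, j]
                if mu == 2.0 and nu == 1.0:
                    # fast path for the common (mu, nu) = (2, 1): everything
                    # is a polynomial in 1/r^2, no pow/sqrt needed
                    inv2 = 1.0 / r2
                    x4 = (sig * sig * inv2) ** 2
                    y4 = (wf_rc * wf_rc * inv2) ** 2
                    t1 = x4 - 1.0
                    t2 = y4 - 1.0
                    energy += ea * t1 * t2 * t2
                    du_r = ea * (-4.0 * x4 * inv2 * t2 * t2
                                 - t1 * 8.0 * t2 * y4 * inv2)
                    fr += -du_r
                else:
                    r = math.sqrt(r2)
                    x2m = (sig / r) ** (2.0 * mu)
                    y2m = (wf_rc / r) ** (2.0 * mu)
                    t1 = x2m - 1.0
                    t2 = y2m - 1.0
                    g = t2 ** (2.0 * nu)
                    energy += ea * t1 * g
                    du = ea * (-(2.0 * mu) * x2m / r * g
                               + t1 * (2.0 * nu) * t2 ** (2.0 * nu - 1.0)
                               * (-(2.0 * mu) * y2m / r))
                    fr += -du / r
            A = qqpref[i, j]
            if A != 0.0 and r2 < el_rc2:
                r = math.sqrt(r2)
                ex = math.exp(-r * inv_ld)
                energy += A * (ex / r - math.exp(-el_rc * inv_ld) / el_rc)
                fr += A * ex * (1.0 / r2 + inv_ld / r) / r
            if fr != 0.0:
                f[i, 0] += fr * dx; f[i, 1] += fr * dy; f[i, 2] += fr * dz
                f[j, 0] -= fr * dx; f[j, 1] -= fr * dy; f[j, 2] -= fr * dz
    for bnd in range(bonds.shape[0]):
        i = bonds[bnd, 0]; j = bonds[bnd, 1]
        dx = pos[i, 0] - pos[j, 0]; dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        # bonded beads are never split by the minimum-image convention in
        # practice (bond << box/2), but apply it for safety
        dx -= box * round(dx / box); dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r = math.sqrt(dx*dx + dy*dy + dz*dz)
        dr = r - bond_r0[bnd]
        energy += 0.5 * bond_k[bnd] * dr * dr
        if r > 1e-12:
            fr = -bond_k[bnd] * dr / r
            f[i, 0] += fr * dx; f[i, 1] += fr * dy; f[i, 2] += fr * dz
            f[j, 0] -= fr * dx; f[j, 1] -= fr * dy; f[j, 2] -= fr * dz
    return energy


@njit(cache=True)
def _body_force_torque(pos, f, nrig, r_start, r_end, com, quat, F, Tb):
    R = np.empty((3, 3))
    for b in range(nrig):
        _quat_to_mat(quat[b], R)
        fx = 0.0; fy = 0.0; fz = 0.0
        tx = 0.0; ty = 0.0; tz = 0.0
        for i in range(r_start[b], r_end[b]):
            fx += f[i, 0]; fy += f[i, 1]; fz += f[i, 2]
            rx = pos[i, 0] - com[b, 0]; ry = pos[i, 1] - com[b, 1]
            rz = pos[i, 2] - com[b, 2]
            tx += ry * f[i, 2] - rz * f[i, 1]
            ty += rz * f[i, 0] - rx * f[i, 2]
            tz += rx * f[i, 1] - ry * f[i, 0]
        F[b, 0] = fx; F[b, 1] = fy; F[b, 2] = fz
        # body-frame torque: R^T tau_lab
        Tb[b, 0] = R[0, 0]*tx + R[1, 0]*ty + R[2, 0]*tz
        Tb[b, 1] = R[0, 1]*tx + R[1, 1]*ty + R[2, 1]*tz
        Tb[b, 2] = R[0, 2]*tx + R[1, 2]*ty + R[2, 2]*tz


@njit(cache=True)
def _integrate(pos, vel, mass, is_flex,
               nrig, r_start, r_end, bodyc, quat, com, comv, omega,
               inertia, bmass,
               excl, eps2d, sig2d, mu2d, nu2d, alpha2d, qqpref, inv_ld, el_rc,
               bonds, bond_k, bond_r0,
               box, dt, gamma, kt, n_steps, save_every,
               frames, temps, save_offset, seed):
    """BAOAB Langevin. Returns step index of numerical blow-up, or -1."""
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    F = np.zeros((nrig if nrig > 0 else 1, 3))
    Tb = np.zeros((nrig if nrig > 0 else 1, 3))
    tmpq = np.empty(4)
    rv = np.empty(3)
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    _reconstruct(pos, nrig, r_start, r_end, bodyc, quat, com)
    _forces(pos, box, excl, eps2d, sig2d, mu2d, nu2d, alpha2d, qqpref,
            inv_ld, el_rc, bonds, bond_k, bond_r0, f)
    if nrig > 0:
        _body_force_torque(pos, f, nrig, r_start, r_end, com, quat, F, Tb)
    nsaved = save_offset
    for step in range(n_steps):
        # B
        for i in range(n):
            if is_flex[i]:
                h = 0.5 * dt / mass[i]
                vel[i, 0] += h * f[i, 0]; vel[i, 1] += h * f[i, 1]
                vel[i, 2] += h * f[i, 2]
        for b in range(nrig):
            h = 0.5 * dt / bmass[b]
            for k in range(3):
                comv[b, k] += h * F[b, k]
            # Euler equations with gyroscopic term, principal frame
            wx, wy, wz = omega[b, 0], omega[b, 1], omega[b, 2]
            Ix, Iy, Iz = inertia[b, 0], inertia[b, 1], inertia[b, 2]
            omega[b, 0] += 0.5 * dt * (Tb[b, 0] - (Iz - Iy) * wy * wz) / Ix
            omega[b, 1] += 0.5 * dt * (Tb[b, 1] - (Ix - Iz) * wz * wx) / Iy
            omega[b, 2] += 0.5 * dt * (Tb[b, 2] - (Iy - Ix) * wx * wy) / Iz
        # A
        for i in range(n):
            if is_flex[i]:
                pos[i, 0] += 0.5 * dt * vel[i, 0]
                pos[i, 1] += 0.5 * dt * vel[i, 1]
                pos[i, 2] += 0.5 * dt * vel[i, 2]
        for b in range(nrig):
            for k in range(3):
                com[b, k] += 0.5 * dt * comv[b, k]
                rv[k] = 0.5 * dt * omega[b, k]
            _rotvec_quat(rv, tmpq)
            q0 = quat[b].copy()
            _quat_mul(q0, tmpq, quat[b])
        # O
        for i in range(n):
            if is_flex[i]:
                s = c2 * math.sqrt(kt / mass[i])
                vel[i, 0] = c1 * vel[i, 0] + s * np.random.normal(0.0, 1.0)
                vel[i, 1] = c1 * vel[i, 1] + s * np.random.normal(0.0, 1.0)
                vel[i, 2] = c1 * vel[i, 2] + s * np.random.normal(0.0, 1.0)
        for b in range(nrig):
            s = c2 * math.sqrt(kt / bmass[b])
            for k in range(3):
                comv[b, k] = c1 * comv[b, k] + s * np.random.normal(0.0, 1.0)
            for k in range(3):
                sk = c2 * math.sqrt(kt / inertia[b, k])
                omega[b, k] = c1 * omega[b, k] + sk * np.random.normal(0.0, 1.0)
        # A
        for i in range(n):
            if is_flex[i]:
                pos[i, 0] += 0.5 * dt * vel[i, 0]
                pos[i, 1] += 0.5 * dt * vel[i, 1]
                pos[i, 2] += 0.5 * dt * vel[i, 2]
        for b in range(nrig):
            for k in range(3):
                com[b, k] += 0.5 * dt * comv[b, k]
                rv[k] = 0.5 * dt * omega[b, k]
            _rotvec_quat(rv, tmpq)
            q0 = quat[b].copy()
            _quat_mul(q0, tmpq, quat[b])
            qn = math.sqrt(quat[b, 0]**2 + quat[b, 1]**2
                           + quat[b, 2]**2 + quat[b, 3]**2)
            for k in range(4):
                quat[b, k] /= qn
        # forces at new positions
        _reconstruct(pos, nrig, r_start, r_end, bodyc, quat, com)
        _forces(pos, box, excl, eps2d, sig2d, mu2d, nu2d, alpha2d, qqpref,
                inv_ld, el_rc, bonds, bond_k, bond_r0, f)
        if nrig > 0:
            _body_force_torque(pos, f, nrig, r_start, r_end, com, quat, F, Tb)
        # B
        for i in range(n):
            if is_flex[i]:
                h = 0.5 * dt / mass[i]
                vel[i, 0] += h * f[i, 0]; vel[i, 1] += h * f[i, 1]
                vel[i, 2] += h * f[i, 2]
        for b in range(nrig):
            h = 0.5 * dt / bmass[b]
            for k in range(3):
                comv[b, k] += h * F[b, k]
            wx, wy, wz = omega[b, 0], omega[b, 1], omega[b, 2]
            Ix, Iy, Iz = inertia[b, 0], inertia[b, 1], inertia[b, 2]
            omega[b, 0] += 0.5 * dt * (Tb[b, 0] - (Iz - Iy) * wy * wz) / Ix
            omega[b, 1] += 0.5 * dt * (Tb[b, 1] - (Ix - Iz) * wz * wx) / Iy
            omega[b, 2] += 0.5 * dt * (Tb[b, 2] - (Iy - Ix) * wx * wy) / Iz
        if (step + 1) % save_every == 0:
            ok = True
            ke = 0.0
            ndof = 0
            for i in range(n):
                if is_flex[i]:
                    ke += 0.5 * mass[i] * (vel[i, 0]**2 + vel[i, 1]**2
                                           + vel[i, 2]**2)
                    ndof += 3
                if not (math.isfinite(pos[i, 0]) and math.isfinite(pos[i, 1])
                        and math.isfinite(pos[i, 2])):
                    ok = False
            for b in range(nrig):
                ke += 0.5 * bmass[b] * (comv[b, 0]**2 + comv[b, 1]**2
                                        + comv[b, 2]**2)
                for k in range(3):
                    ke += 0.5 * inertia[b, k] * omega[b, k]**2
                ndof += 6
            if not ok:
                return step
            if nsaved < frames.shape[0]:
                for i in range(n):
                    for k in range(3):
                        frames[nsaved, i, k] = pos[i, k]
                temps[nsaved] = 2.0 * ke / (ndof * 0.00831446)
                nsaved += 1
    return -1


@njit(cache=True)
def _minimize(pos, is_flex, nrig, r_start, r_end, bodyc, quat, com,
              excl, eps2d, sig2d, mu2d, nu2d, alpha2d, qqpref, inv_ld, el_rc,
              bonds, bond_k, bond_r0, box, n_iter, step_cap):
    """Capped-displacement steepest descent to relax initial overlaps.

    Flexible beads move individually; rigid bodies translate along their net
    force (no rotation needed just to resolve clashes)."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    for _ in range(n_iter):
        _reconstruct(pos, nrig, r_start, r_end, bodyc, quat, com)
        _forces(pos, box, excl, eps2d, sig2d, mu2d, nu2d, alpha2d, qqpref,
                inv_ld, el_rc, bonds, bond_k, bond_r0, f)
        for i in range(n):
            if is_flex[i]:
                fn = math.sqrt(f[i, 0]**2 + f[i, 1]**2 + f[i, 2]**2)
                if fn > 1e-12:
                    s = min(step_cap, 1e-4 * fn) / fn
                    pos[i, 0] += s * f[i, 0]
                    pos[i, 1] += s * f[i, 1]
                    pos[i, 2] += s * f[i, 2]
        for b in range(nrig):
            fx = 0.0; fy = 0.0; fz = 0.0
            for i in range(r_start[b], r_end[b]):
                fx += f[i, 0]; fy += f[i, 1]; fz += f[i, 2]
            fn = math.sqrt(fx*fx + fy*fy + fz*fz)
            if fn > 1e-12:
                s = min(step_cap, 1e-4 * fn) / fn
                com[b, 0] += s * fx; com[b, 1] += s * fy; com[b, 2] += s * fz
    _reconstruct(pos, nrig, r_start, r_end, bodyc, quat, com)


# --------------------------------------------------------------------------
# setup and driver
# --------------------------------------------------------------------------

def _pair_tables(top: Topology, cfg: SimConfig):
    n = top.n_beads
    sig = top.bead_array("sigma")
    eps = top.bead_array("epsilon")
    mu = top.bead_array("mu")
    nu = top.bead_array("nu")
    q = top.bead_array("charge")
    sig2d = 0.5 * (sig[:, None] + sig[None, :])
    eps2d = np.sqrt(eps[:, None] * eps[None, :])
    mu2d = 0.5 * (mu[:, None] + mu[None, :])
    nu2d = 0.5 * (nu[:, None] + nu[None, :])
    alpha2d = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            alpha2d[i, j] = _wf_alpha(3.0, mu2d[i, j], nu2d[i, j])
    lb = bjerrum_length_nm(cfg.temperature, cfg.dielectric)
    qqpref = q[:, None] * q[None, :] * lb * cfg.kt
    excl = np.zeros((n, n), dtype=np.uint8)
    for i, j in top.bonds:
        excl[i, j] = excl[j, i] = 1
    ci = top.chain_index()
    for r in top.rigid_chains():
        idx = np.flatnonzero(ci == r)
        excl[np.ix_(idx, idx)] = 1
    np.fill_diagonal(excl, 1)
    return sig2d, eps2d, mu2d, nu2d, alpha2d, qqpref, excl


def _principal_frame(coords: np.ndarray, masses: np.ndarray):
    """COM, principal inertia moments, rotation matrix (columns = axes),
    body-frame coordinates."""
    m = masses[:, None]
    com = (coords * m).sum(axis=0) / masses.sum()
    rel = coords - com
    inertia = np.zeros((3, 3))
    for k in range(len(masses)):
        r = rel[k]
        inertia += masses[k] * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    w, v = np.linalg.eigh(inertia)
    if np.linalg.det(v) < 0:
        v[:, 2] *= -1
    w = np.maximum(w, 1e-6)
    body = rel @ v
    return com, w, v, body


def _mat_to_quat(R: np.ndarray) -> np.ndarray:
    t = np.trace(R)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2
        q = np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                      (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1.0 + R[i, i] - R[j, j] - R[k, k], 1e-12)) * 2
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    return q / np.linalg.norm(q)


def _init_state(top: Topology, cfg: SimConfig, conformer_index: int,
                rng: np.random.Generator):
    """Initial coordinates: each flexible chain as a bond-length random walk,
    rigid bodies at random orientation; chain centers separated."""
    n = top.n_beads
    pos = np.zeros((n, 3))
    masses = top.bead_array("mass")
    nchain = len(top.chains)
    offset = 0
    rigid_state = []
    for c_idx, chain in enumerate(top.chains):
        nb = chain.n_beads
        sl = slice(offset, offset + nb)
        center = np.full(3, cfg.box_edge * 0.5)
        center[0] += (c_idx - 0.5 * (nchain - 1)) * cfg.box_edge * 0.3
        if chain.flexible:
            r0 = top.bond_r0[0] if len(top.bond_r0) else 0.4
            walk = np.zeros((nb, 3))
            min_sep = 0.9 * min(bt.sigma for bt in chain.bead_types)
            for i in range(1, nb):
                for _try in range(200):
                    v = rng.normal(size=3)
                    cand = walk[i - 1] + r0 * v / np.linalg.norm(v)
                    if i < 2 or np.min(np.linalg.norm(walk[:i - 1] - cand,
                                                      axis=1)) > min_sep:
                        break
                walk[i] = cand
            pos[sl] = walk - walk.mean(axis=0) + center
        else:
            coords = chain.conformers[conformer_index]
            com0, w, v, body = _principal_frame(coords, masses[sl])
            # random initial orientation
            u = rng.normal(size=4)
            u /= np.linalg.norm(u)
            Rq = np.empty((3, 3))
            _quat_to_mat(u, Rq)
            pos[sl] = center + body @ Rq.T
            rigid_state.append({
                "slice": sl, "body": body, "inertia": w,
                "quat": _mat_to_quat(Rq), "com": center.astype(float),
                "mass": masses[sl].sum(),
            })
        offset += nb
    return pos, rigid_state


def potential_energy(top: Topology, pos: np.ndarray, cfg: SimConfig) -> float:
    """Total potential energy (kJ/mol) of a configuration, same terms as the
    engine (used for conformer-swap Metropolis tests and unit checks)."""
    sig2d, eps2d, mu2d, nu2d, alpha2d, qqpref, excl = _pair_tables(top, cfg)
    ld = debye_length_nm(cfg.ionic_strength, cfg.temperature, cfg.dielectric)
    f = np.zeros_like(pos)
    return float(_forces(np.ascontiguousarray(pos, dtype=np.float64),
                         cfg.box_edge, excl, eps2d, sig2d, mu2d, nu2d,
                         alpha2d, qqpref, 1.0 / ld, cfg.nonbonded_cutoff,
                         top.bonds, top.bond_k, top.bond_r0, f))


def run_simulation(top: Topology, config: SimConfig,
                   conformer_index: int = 0) -> Trajectory:
    """Integrate Langevin dynamics and return the saved production frames.

    The first ``equilibration_fraction * n_steps`` steps are run and
    discarded before production; production saves every ``save_every`` steps,
    so the returned trajectory has ``n_steps // save_every`` frames. Runs are
    bitwise reproducible for a fixed (topology, config, conformer) triple.

    For a multi-conformer rigid chain with ``conformer_mode='swap'`` the rigid
    coordinates are exchanged by seeded Metropolis Monte Carlo every
    ``swap_every`` steps; otherwise the given conformer is simulated alone
    (pool over conformers with :func:`simulate_conformers`).
    """
    cfg = config
    rigid = top.rigid_chains()
    multi = [i for i in rigid
             if top.chains[i].conformers is not None
             and top.chains[i].conformers.shape[0] > 1]
    if cfg.conformer_mode == "swap" and multi:
        return _run_with_swaps(top, cfg, conformer_index)
    return _run_single(top, cfg, conformer_index)


def _kernel_inputs(top, cfg, pos, rigid_state, rng):
    n = top.n_beads
    masses = top.bead_array("mass")
    ci = top.chain_index()
    rigid_chain_ids = set(top.rigid_chains())
    is_flex = np.array([ci[i] not in rigid_chain_ids for i in range(n)],
                       dtype=np.bool_)
    vel = np.zeros((n, 3))
    vel[is_flex] = rng.normal(size=(int(is_flex.sum()), 3)) * \
        np.sqrt(cfg.kt / masses[is_flex])[:, None]
    nrig = len(rigid_state)
    r_start = np.array([rs["slice"].start for rs in rigid_state], dtype=np.int64)
    r_end = np.array([rs["slice"].stop for rs in rigid_state], dtype=np.int64)
    bodyc = np.zeros((n, 3))
    quat = np.zeros((max(nrig, 1), 4)); quat[:, 0] = 1.0
    com = np.zeros((max(nrig, 1), 3))
    comv = np.zeros((max(nrig, 1), 3))
    omega = np.zeros((max(nrig, 1), 3))
    inertia = np.ones((max(nrig, 1), 3))
    bmass = np.ones(max(nrig, 1))
    for b, rs in enumerate(rigid_state):
        bodyc[rs["slice"]] = rs["body"]
        quat[b] = rs["quat"]
        com[b] = rs["com"]
        inertia[b] = rs["inertia"]
        bmass[b] = rs["mass"]
        comv[b] = rng.normal(size=3) * math.sqrt(cfg.kt / rs["mass"])
        omega[b] = rng.normal(size=3) * np.sqrt(cfg.kt / rs["inertia"])
    return (masses, is_flex, nrig, r_start, r_end, bodyc, quat, com, comv,
            omega, inertia, bmass, vel)


def _run_single(top: Topology, cfg: SimConfig, conformer_index: int) -> Trajectory:
    rng = np.random.default_rng(cfg.seed)
    pos, rigid_state = _init_state(top, cfg, conformer_index, rng)
    (masses, is_flex, nrig, r_start, r_end, bodyc, quat, com, comv, omega,
     inertia, bmass, vel) = _kernel_inputs(top, cfg, pos, rigid_state, rng)
    sig2d, eps2d, mu2d, nu2d, alpha2d, qqpref, excl = _pair_tables(top, cfg)
    ld = debye_length_nm(cfg.ionic_strength, cfg.temperature, cfg.dielectric)

    _minimize(pos, is_flex, nrig, r_start, r_end, bodyc, quat, com,
              excl, eps2d, sig2d, mu2d, nu2d, alpha2d, qqpref, 1.0 / ld,
              cfg.nonbonded_cutoff, top.bonds, top.bond_k, top.bond_r0,
              cfg.box_edge, 500, 0.02)

    n_equil = int(round(cfg.equilibration_fraction * cfg.n_steps))
    n_save = cfg.n_steps // cfg.save_every
    frames = np.zeros((n_save, top.n_beads, 3))
    temps = np.zeros(n_save)
    kseed = int((cfg.seed * 9973 + conformer_index * 131 + 7) % (2**31 - 1))

    def call(nsteps, save_every, offset, seed):
        return _integrate(
            pos, vel, masses, is_flex, nrig, r_start, r_end, bodyc, quat,
            com, comv, omega, inertia, bmass, excl, eps2d, sig2d, mu2d,
            nu2d, alpha2d, qqpref, 1.0 / ld, cfg.nonbonded_cutoff,
            top.bonds, top.bond_k, top.bond_r0, cfg.box_edge, cfg.timestep,
            cfg.friction, cfg.kt, nsteps, save_every, frames, temps,
            offset, seed)

    if n_equil:
        bad = call(n_equil, n_equil + 1, n_save, kseed)  # never saves
        if bad >= 0:
            raise IntegrationError(f"non-finite coordinates at equilibration step {bad}")
    bad = call(cfg.n_steps, cfg.save_every, 0, kseed + 1)
    if bad >= 0:
        raise IntegrationError(f"non-finite coordinates at production step {bad}")
    return Trajectory(
        frames=frames, box_edge=cfg.box_edge, chain_index=top.chain_index(),
        chain_ids=[c.chain_id for c in top.chains], stride=cfg.save_every,
        config=asdict(cfg), sigmas=top.bead_array("sigma"),
        charges=top.bead_array("charge"),
        temperatures=temps, conformer_index=conformer_index)


def _run_with_swaps(top: Topology, cfg: SimConfig, conformer_index: int) -> Trajectory:
    """Conformer-swap Monte Carlo interleaved with dynamics chunks."""
    rng = np.random.default_rng(cfg.seed)
    pos, rigid_state = _init_state(top, cfg, conformer_index, rng)
    (masses, is_flex, nrig, r_start, r_end, bodyc, quat, com, comv, omega,
     inertia, bmass, vel) = _kernel_inputs(top, cfg, pos, rigid_state, rng)
    sig2d, eps2d, mu2d, nu2d, alpha2d, qqpref, excl = _pair_tables(top, cfg)
    ld = debye_length_nm(cfg.ionic_strength, cfg.temperature, cfg.dielectric)

    # the single multi-conformer body
    bidx = None
    for b, r in enumerate(top.rigid_chains()):
        if top.chains[r].conformers.shape[0] > 1:
            bidx, chain_r = b, r
    confs = top.chains[chain_r].conformers
    current = conformer_index

    _minimize(pos, is_flex, nrig, r_start, r_end, bodyc, quat, com,
              excl, eps2d, sig2d, mu2d, nu2d, alpha2d, qqpref, 1.0 / ld,
              cfg.nonbonded_cutoff, top.bonds, top.bond_k, top.bond_r0,
              cfg.box_edge, 500, 0.02)

    n_equil = int(round(cfg.equilibration_fraction * cfg.n_steps))
    n_save = cfg.n_steps // cfg.save_every
    frames = np.zeros((n_save, top.n_beads, 3))
    temps = np.zeros(n_save)
    kseed = int((cfg.seed * 9973 + 7) % (2**31 - 1))
    chunk = max(cfg.swap_every, cfg.save_every)
    chunk -= chunk % cfg.save_every

    def run_chunk(nsteps, save_every, offset, seed):
        bad = _integrate(
            pos, vel, masses, is_flex, nrig, r_start, r_end, bodyc, quat,
            com, comv, omega, inertia, bmass, excl, eps2d, sig2d, mu2d,
            nu2d, alpha2d, qqpref, 1.0 / ld, cfg.nonbonded_cutoff,
            top.bonds, top.bond_k, top.bond_r0, cfg.box_edge, cfg.timestep,
            cfg.friction, cfg.kt, nsteps, save_every, frames, temps,
            offset, seed)
        if bad >= 0:
            raise IntegrationError(f"non-finite coordinates at step {bad}")

    def attempt_swap():
        nonlocal current
        proposal = int(rng.integers(0, confs.shape[0]))
        if proposal == current:
            return
        sl = slice(int(r_start[bidx]), int(r_end[bidx]))
        _reconstruct(pos, nrig, r_start, r_end, bodyc, quat, com)
        u_old = potential_energy(top, pos, cfg)
        # superpose proposed conformer onto current pose (Kabsch)
        cur = pos[sl] - pos[sl].mean(axis=0)
        new = confs[proposal] - confs[proposal].mean(axis=0)
        H = new.T @ cur
        U, _s, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        placed = (new @ R.T) + pos[sl].mean(axis=0)
        trial = pos.copy()
        trial[sl] = placed
        u_new = potential_energy(top, trial, cfg)
        if rng.random() < math.exp(min(0.0, -(u_new - u_old) / cfg.kt)):
            current = proposal
            m = masses[sl]
            com_b, w, v, body = _principal_frame(placed, m)
            bodyc[sl] = body
            quat[bidx] = _mat_to_quat(v)
            com[bidx] = com_b
            inertia[bidx] = w
            omega[bidx] = rng.normal(size=3) * np.sqrt(cfg.kt / w)
            pos[sl] = placed

    if n_equil:
        run_chunk(n_equil, n_equil + 1, n_save, kseed)
    done = 0
    ck = 0
    while done < cfg.n_steps:
        nstep = min(chunk, cfg.n_steps - done)
        run_chunk(nstep, cfg.save_every, done // cfg.save_every, kseed + 1 + ck)
        done += nstep
        ck += 1
        if done < cfg.n_steps:
            attempt_swap()
    return Trajectory(
        frames=frames, box_edge=cfg.box_edge, chain_index=top.chain_index(),
        chain_ids=[c.chain_id for c in top.chains], stride=cfg.save_every,
        config=asdict(cfg), sigmas=top.bead_array("sigma"),
        charges=top.bead_array("charge"),
        temperatures=temps, conformer_index=None)


def simulate_conformers(top: Topology, config: SimConfig,
                        conformer_indices=None) -> list[Trajectory]:
    """Separate runs per rigid conformer (pooled-statistics protocol).

    Each conformer gets its own seed stream derived from ``config.seed``.
    """
    rigid = [i for i in top.rigid_chains()
             if top.chains[i].conformers is not None]
    if not rigid:
        return [run_simulation(top, config)]
    n_conf = top.chains[rigid[0]].conformers.shape[0]
    if conformer_indices is None:
        conformer_indices = range(n_conf)
    out = []
    for idx in conformer_indices:
        cfg_i = SimConfig(**{**asdict(config),
                             "seed": int((config.seed + 1000 * (idx + 1)) % (2**31 - 1))})
        out.append(run_simulation(top, cfg_i, conformer_index=idx))
    return out
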