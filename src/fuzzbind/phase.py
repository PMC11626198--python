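"""Turbidity-based coacervation analysis.

Turbidity at 340 nm is treated as an arbitrary-units order parameter for
phase separation: titration curves yield the stoichiometric ratio at which
turbidity peaks (expected near the charge-matched protein:RNA ratio for
complex coacervation), salt series test the electrostatic hallmark of a
monotone turbidity decrease with ionic strength, and a concentration grid of
turbidity readings assembles into a two-phase diagram by thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TurbidityCurve", "PhaseDiagramGrid", "titration_features",
           "salt_dependence", "assemble_phase_diagram"]


@dataclass
class TurbidityCurve:
    """Absorbance-at-340-nm readings versus titrant concentration or molar ratio."""

    x: np.ndarray
    a340: np.ndarray
    fixed_component: str = ""
    fixed_concentration_uM: float = 0.0
    nacl_mM: float = 0.0
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if len(self.x) != len(self.a340):
            raise ValueError("x and a340 lengths differ")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly ascending")
        if np.any(self.a340 < 0):
            raise ValueError("a340 must be >= 0")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"x": self.x, "a340": self.a340})
        if self.sd is not None:
            df["sd"] = self.sd
        df["nacl_mM"] = self.nacl_mM
        df.to_csv(path, index=False)


def _moving_average(y: np.ndarray, window: int = 3) -> np.ndarray:
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def _noise_scale(curve: TurbidityCurve) -> float:
    if curve.sd is not None and np.all(np.isfinite(curve.sd)):
        return float(np.median(curve.sd))
    # robust residual scale about the 3-point moving average
    resid = curve.a340 - _moving_average(curve.a340)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    return 1.4826 * mad if mad > 0 else 1e-12


def titration_features(curve: TurbidityCurve, baseline_points: int = 3) -> dict:
    """Peak/plateau position, maximum signal and onset of a turbidity titration.

    The curve is smoothed with a 3-point moving average before locating the
    maximum. The onset is the first x whose signal exceeds baseline + 3 sd.
    A flat curve returns ``transition=False`` rather than raising.
    """
    if len(curve.x) < 6:
        raise ValueError("need at least 6 titration points")
    smooth = _moving_average(curve.a340)
    noise = _noise_scale(curve)
    baseline = float(np.min(smooth[:baseline_points]))
    max_a340 = float(smooth.max())
    if max_a340 - baseline < 3 * noise or max_a340 <= baseline:
        return {"transition": False, "peak_x": np.nan, "max_a340": max_a340,
                "onset_x": np.nan, "plateau": False}
    ipk = int(np.argmax(smooth))
    plateau = bool(np.all(smooth[-3:] >= max_a340 - 3 * noise))
    above = np.flatnonzero(curve.a340 > baseline + 3 * noise)
    onset = float(curve.x[above[0]]) if len(above) else np.nan
    return {"transition": True, "peak_x": float(curve.x[ipk]),
            "max_a340": max_a340, "onset_x": onset, "plateau": plateau}


def salt_dependence(curves: list[TurbidityCurve]) -> dict:
    """Monotonicity verdict and half-decay midpoint of max turbidity vs NaCl.

    Curves are sorted by their NaCl concentration internally. The midpoint is
    the linearly interpolated salt concentration at which the maximum
    turbidity crosses half its lowest-salt value.
    """
    if len(curves) < 2:
        raise ValueError("need curves at more than one salt concentration")
    order = np.argsort([c.nacl_mM for c in curves])
    salts = np.array([curves[i].nacl_mM for i in order], dtype=float)
    if len(curves) < 4:
        warnings.warn("fewer than 4 salt points; verdict is weakly constrained")
    maxima = np.array([float(np.max(curves[i].a340)) for i in order])
    decreasing = bool(np.all(np.diff(maxima) < 0))
    half = maxima[0] / 2.0
    midpoint = np.nan
    for k in range(len(maxima) - 1):
        y0, y1 = maxima[k], maxima[k + 1]
        if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
            t = (half - y0) / (y1 - y0)
            midpoint = float(salts[k] + t * (salts[k + 1] - salts[k]))
            break
    return {"monotone_decreasing": decreasing, "midpoint_mM": midpoint,
            "max_turbidity": maxima, "nacl_mM": salts}


@dataclass
class PhaseDiagramGrid:
    """Rectangular protein x RNA concentration grid of mean turbidity."""

    c_protein_uM: np.ndarray
    c_rna_uM: np.ndarray
    turbidity: np.ndarray            # (n_protein, n_rna), NaN = missing cell
    threshold: float
    two_phase: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        self.two_phase = self.turbidity > self.threshold

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.turbidity, index=self.c_protein_uM,
                          columns=self.c_rna_uM)
        df.index.name = "c_protein_uM\\c_rna_uM"
        df.to_csv(path, sep="\t")


def assemble_phase_diagram(measurements, threshold: float | None = None,
                           baseline_sd_factor: float = 5.0) -> tuple[PhaseDiagramGrid, list]:
    """Build a phase diagram from (c_protein_uM, c_rna_uM, a340) triples.

    Duplicate grid cells are averaged (with a warning). The two-phase call is
    a340 > threshold; the default threshold is baseline + 5 x baseline SD,
    where the baseline statistics come from the lowest-concentration row and
    column. Returns the grid plus boundary points (threshold crossings along
    each row and column, linearly interpolated).
    """
    meas = [(float(a), float(b), float(t)) for a, b, t in measurements]
    if len({(a, b) for a, b, _ in meas}) < 4:
        raise ValueError("need at least 4 distinct grid points")
    cp = np.array(sorted({m[0] for m in meas}))
    cr = np.array(sorted({m[1] for m in meas}))
    grid = np.full((len(cp), len(cr)), np.nan)
    counts = np.zeros_like(grid)
    for a, b, t in meas:
        i = int(np.searchsorted(cp, a)); j = int(np.searchsorted(cr, b))
        if counts[i, j] > 0:
            warnings.warn(f"duplicate grid cell ({a}, {b}); averaging")
            grid[i, j] = (grid[i, j] * counts[i, j] + t) / (counts[i, j] + 1)
        else:
            grid[i, j] = t
        counts[i, j] += 1
    if threshold is None:
        edge = np.concatenate([grid[0, :][~np.isnan(grid[0, :])],
                               grid[:, 0][~np.isnan(grid[:, 0])]])
        base, sd = float(np.mean(edge)), float(np.std(edge))
        threshold = base + baseline_sd_factor * max(sd, 1e-12)
    diagram = PhaseDiagramGrid(cp, cr, grid, threshold)
    boundary = []
    for i, row in enumerate(grid):
        for j in range(len(cr) - 1):
            y0, y1 = row[j], row[j + 1]
            if np.isnan(y0) or np.isnan(y1):
                continue
            if (y0 - threshold) * (y1 - threshold) < 0:
                t = (threshold - y0) / (y1 - y0)
                boundary.append((float(cp[i]),
                                 float(cr[j] + t * (cr[j + 1] - cr[j]))))
    for j in range(len(cr)):
        col = grid[:, j]
        for i in range(len(cp) - 1):
            y0, y1 = col[i], col[i + 1]
            if np.isnan(y0) or np.isnan(y1):
                continue
            if (y0 - threshold) * (y1 - threshold) < 0:
                t = (threshold - y0) / (y1 - y0)
                boundary.append((float(cp[i] + t * (cp[i + 1] - cp[i])),
                                 float(cr[j])))
    return diagram, boundary
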