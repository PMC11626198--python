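"""Equilibrium anisotropy binding models and nonlinear isotherm fitting.

A fluorescence-anisotropy titration follows a labeled RNA probe at fixed total
concentration R_t while the protein titrant P_t increases. For 1:1 binding
with ligand depletion the complex concentration solves the mass-balance
quadratic exactly,

    [PR] = ((P_t + R_t + K_D) - sqrt((P_t + R_t + K_D)^2 - 4 P_t R_t)) / 2,

and the observed anisotropy is the population-weighted endpoint mixture
r = r_free + (r_bound - r_free) * [PR]/R_t. The sequential 2:1 model adds a
second protein-binding step P + PR <=> P2R with macroscopic constants K1, K2
and is solved by numeric root-finding on free protein. Fits are weighted
least squares with confidence intervals from the linearized covariance
(bootstrap optional); model comparison uses the small-sample-corrected Akaike
criterion.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["TitrationSeries", "BindingFit", "anisotropy_model",
           "fraction_bound_1to1", "fit_isotherm", "compare_models",
           "UnidentifiabilityError"]


class UnidentifiabilityError(RuntimeError):
    """The data do not constrain the binding parameters."""


@dataclass
class TitrationSeries:
    """Anisotropy titration: fixed labeled probe, ascending titrant."""

    probe_total: float                 # M
    titrant_totals: np.ndarray         # M, ascending
    anisotropy: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self):
        self.titrant_totals = np.asarray(self.titrant_totals, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
            if len(self.replicate_sd) != len(self.titrant_totals):
                raise ValueError("replicate_sd length mismatch")
        if len(self.titrant_totals) != len(self.anisotropy):
            raise ValueError("titrant and anisotropy lengths differ")
        if self.probe_total < 0 or np.any(self.titrant_totals < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(self.titrant_totals) <= 0):
            raise ValueError("titrant concentrations must be strictly ascending")
        if not np.all(np.isfinite(self.anisotropy)):
            raise ValueError("anisotropy must be finite")

    def __len__(self):
        return len(self.titrant_totals)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"titrant_M": self.titrant_totals,
                           "anisotropy": self.anisotropy})
        if self.replicate_sd is not None:
            df["sd"] = self.replicate_sd
        df.attrs["probe_M"] = self.probe_total
        with open(path, "w") as fh:
            fh.write(f"# probe_M = {self.probe_total:.6g}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TitrationSeries":
        probe = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                probe = float(first.split("=")[1])
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        if probe is None:
            raise ValueError("missing '# probe_M = ...' header line")
        return cls(probe_total=probe,
                   titrant_totals=df["titrant_M"].to_numpy(),
                   anisotropy=df["anisotropy"].to_numpy(),
                   replicate_sd=df["sd"].to_numpy() if "sd" in df else None)


@dataclass
class BindingFit:
    """Fitted binding-model parameters. kd_app is one value (1:1) or the pair
    (K1, K2) for the sequential 2:1 model; endpoints analogous."""

    model: str                          # "one_to_one" | "two_to_one"
    kd_app: tuple[float, ...]
    r_free: float
    r_bound: tuple[float, ...]
    ci: dict = field(default_factory=dict)   # param -> (lo, hi), 95%
    rss: float = 0.0
    n_points: int = 0
    n_params: int = 0
    aicc: float = np.nan

    def __post_init__(self):
        if any(k <= 0 for k in self.kd_app):
            raise ValueError("kd_app must be > 0")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["ci"] = {k: list(v) for k, v in d["ci"].items()}
        s = json.dumps(d, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def fraction_bound_1to1(probe_total, titrant_total, kd):
    """Exact fraction of probe bound, ligand depletion included (vectorized)."""
    p = np.asarray(titrant_total, dtype=float)
    r = probe_total
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if np.any(p < 0) or r < 0:
        raise ValueError("concentrations must be >= 0")
    if r == 0:
        return p / (p + kd)  # infinite-dilution probe limit
    b = p + r + kd
    disc = b * b - 4.0 * p * r
    complex_ = 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))
    complex_ = np.clip(complex_, 0.0, np.minimum(p, r))
    return complex_ / r


def _species_2to1(probe_total, titrant_total, k1, k2):
    """Free-protein root and species concentrations for P+R<=>PR, P+PR<=>P2R."""
    r_t, p_t = probe_total, titrant_total
    if p_t == 0:
        return 0.0, r_t, 0.0, 0.0

    def balance(p):
        denom = 1.0 + p / k1 + p * p / (k1 * k2)
        r = r_t / denom
        return p + r * (p / k1) + 2.0 * r * (p * p / (k1 * k2)) - p_t

    try:
        p_free = optimize.brentq(balance, 0.0, p_t, xtol=1e-18, rtol=1e-14)
    except ValueError as exc:  # pragma: no cover - bracketing always valid
        raise RuntimeError(f"2:1 mass-balance root not bracketed: {exc}")
    denom = 1.0 + p_free / k1 + p_free ** 2 / (k1 * k2)
    r_free = r_t / denom
    pr = r_free * p_free / k1
    p2r = r_free * p_free ** 2 / (k1 * k2)
    return p_free, r_free, pr, p2r


def anisotropy_model(probe_total, titrant_total, params: dict,
                     model: str = "one_to_one"):
    """Predicted anisotropy at one or many titrant concentrations.

    ``params``: r_free, r_bound, kd (1:1); or r_free, r_bound (scalar or pair),
    k1, k2 (2:1). Vectorized over titrant_total.
    """
    if model == "one_to_one":
        fb = fraction_bound_1to1(probe_total, titrant_total, params["kd"])
        return params["r_free"] + (params["r_bound"] - params["r_free"]) * fb
    if model == "two_to_one":
        k1, k2 = params["k1"], params["k2"]
        if k1 <= 0 or k2 <= 0:
            raise ValueError("binding constants must be > 0")
        rb = params["r_bound"]
        rb1, rb2 = (rb, rb) if np.isscalar(rb) else rb
        p_arr = np.atleast_1d(np.asarray(titrant_total, dtype=float))
        if np.any(p_arr < 0) or probe_total < 0:
            raise ValueError("concentrations must be >= 0")
        out = np.empty_like(p_arr)
        for i, p in enumerate(p_arr):
            _, r_free_c, pr, p2r = _species_2to1(probe_total, p, k1, k2)
            out[i] = (params["r_free"] * r_free_c + rb1 * pr + rb2 * p2r) \
                / probe_total
        return out if np.ndim(titrant_total) else float(out[0])
    raise ValueError(f"unknown model {model!r}")


def _initial_guess(data: TitrationSeries) -> tuple[float, float, float]:
    r_free0 = float(data.anisotropy[0])
    r_bound0 = float(data.anisotropy[-1])
    kd0 = float(np.median(data.titrant_totals))
    return r_free0, r_bound0, kd0


def fit_isotherm(data: TitrationSeries, model: str = "one_to_one",
                 distinct_endpoints: bool = False,
                 bootstrap: int = 0, seed: int = 0) -> BindingFit:
    """Weighted least-squares fit of a binding model to a titration.

    K_D is fit on a log scale to enforce positivity. 95% confidence intervals
    come from the linearized covariance by default; set ``bootstrap`` to a
    positive replicate count for seeded residual-bootstrap intervals.
    """
    if len(data) < 5:
        raise ValueError("need at least 5 titration points")
    y = data.anisotropy
    if np.ptp(y) < 1e-12 or np.std(y) < 1e-4 * max(1.0, abs(np.mean(y))):
        raise UnidentifiabilityError(
            "anisotropy is constant across the titration; no binding "
            "transition to fit (span %.3g)" % np.ptp(y))
    w = None
    if data.replicate_sd is not None and np.all(data.replicate_sd > 0):
        # moderated weights: per-point SDs from small replicate counts are
        # extremely noisy (an occasional near-zero SD would dominate the
        # fit), so shrink the variances halfway toward the pooled variance
        pooled = float(np.mean(data.replicate_sd ** 2))
        w = 1.0 / np.sqrt(0.5 * pooled + 0.5 * data.replicate_sd ** 2)
    x = data.titrant_totals
    r_free0, r_bound0, kd0 = _initial_guess(data)

    if model == "one_to_one":
        names = ["kd", "r_free", "r_bound"]
        p0 = np.array([math.log(kd0), r_free0, r_bound0])

        def predict(theta):
            return anisotropy_model(
                data.probe_total, x,
                {"kd": math.exp(theta[0]), "r_free": theta[1],
                 "r_bound": theta[2]}, "one_to_one")
    elif model == "two_to_one":
        if distinct_endpoints:
            names = ["k1", "k2", "r_free", "r_bound1", "r_bound2"]
            p0 = np.array([math.log(kd0), math.log(kd0), r_free0,
                           r_bound0, r_bound0 * 1.05])
        else:
            names = ["k1", "k2", "r_free", "r_bound"]
            p0 = np.array([math.log(kd0), math.log(kd0), r_free0, r_bound0])

        def predict(theta):
            rb = (theta[3], theta[4]) if distinct_endpoints else theta[3]
            return anisotropy_model(
                data.probe_total, x,
                {"k1": math.exp(theta[0]), "k2": math.exp(theta[1]),
                 "r_free": theta[2], "r_bound": rb}, "two_to_one")
    else:
        raise ValueError(f"unknown model {model!r}")

    def residuals(theta):
        res = predict(theta) - y
        return res * w if w is not None else res

    sol = optimize.least_squares(residuals, p0, method="lm", max_nfev=20000)
    if not sol.success:
        sol = optimize.least_squares(residuals, p0, method="trf", max_nfev=20000)
    if not sol.success:
        raise UnidentifiabilityError(f"fit did not converge: {sol.message}")
    theta = sol.x
    res_unw = predict(theta) - y
    rss = float(np.sum(res_unw ** 2))
    n, k = len(y), len(theta)

    # linearized covariance in the internal (log-kd) parameterization
    ci = {}
    try:
        J = sol.jac
        dof = max(n - k, 1)
        s2 = float(np.sum(sol.fun ** 2)) / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        tcrit = stats.t.ppf(0.975, dof)
        for i, name in enumerate(names):
            lo, hi = theta[i] - tcrit * se[i], theta[i] + tcrit * se[i]
            if name in ("kd", "k1", "k2"):
                # a weakly determined constant can have a huge log-scale SE
                ci[name] = (math.exp(max(lo, -700.0)),
                            math.exp(min(hi, 700.0)))
            else:
                ci[name] = (lo, hi)
    except np.linalg.LinAlgError:
        warnings.warn("singular Jacobian; confidence intervals unavailable")

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = []
        base = predict(theta)
        for _ in range(bootstrap):
            yb = base + rng.choice(res_unw, size=n, replace=True)
            db = TitrationSeries(data.probe_total, x, yb, data.replicate_sd)
            try:
                fb = fit_isotherm(db, model, distinct_endpoints)
                boot.append(fb.kd_app + (fb.r_free,) + fb.r_bound)
            except (UnidentifiabilityError, ValueError):
                continue
        if len(boot) >= max(20, bootstrap // 2):
            barr = np.array(boot)
            for i, name in enumerate(names):
                ci[name] = tuple(np.percentile(barr[:, i], [2.5, 97.5]))

    aicc = _aicc(rss, n, k)
    if model == "one_to_one":
        fit = BindingFit(model=model, kd_app=(math.exp(theta[0]),),
                         r_free=theta[1], r_bound=(theta[2],),
                         ci=ci, rss=rss, n_points=n, n_params=k, aicc=aicc)
    else:
        rb = (theta[3], theta[4]) if distinct_endpoints else (theta[3],)
        fit = BindingFit(model=model,
                         kd_app=(math.exp(theta[0]), math.exp(theta[1])),
                         r_free=theta[2], r_bound=rb,
                         ci=ci, rss=rss, n_points=n, n_params=k, aicc=aicc)
    if all(abs(fit.r_free - rb) < 1e-9 for rb in fit.r_bound):
        raise UnidentifiabilityError("fitted endpoints coincide (flat isotherm)")
    return fit


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def compare_models(fit_1to1: BindingFit, fit_2to1: BindingFit,
                   data: TitrationSeries) -> dict:
    """Small-sample-corrected information-criterion model selection.

    Lower AICc wins; |delta| < 2 is flagged as a tie.
    """
    for f in (fit_1to1, fit_2to1):
        if f.n_points != len(data):
            raise ValueError("fit was not performed on the given data")
    delta = fit_2to1.aicc - fit_1to1.aicc
    preferred = "one_to_one" if delta >= 0 else "two_to_one"
    return {
        "preferred": preferred,
        "aicc_one_to_one": fit_1to1.aicc,
        "aicc_two_to_one": fit_2to1.aicc,
        "delta_aicc": delta,
        "tie": bool(abs(delta) < 2.0),
    }
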