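"""Binding and exchange-kinetics curve fitting.

Two measurement models:

* Nucleotide-exchange fluorescence decay (Mant-GDP release from a GTPase
  driven by a GEF), fitted as a single exponential
  ``y(t) = y_inf + (y_0 - y_inf) exp(-k t)``; GEF activities of variants are
  compared as rate ratios.
* Equilibrium titrations (e.g. microscale thermophoresis dilution series)
  fitted with a 1:1 binding model. The bound fraction uses the exact
  quadratic mass balance, so receptor depletion is handled; it reduces to
  the hyperbola L/(Kd + L) when the receptor concentration is negligible.

All concentrations are molar and times are seconds. Standard errors come
from the Gauss-Newton covariance at the optimum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ExchangeTrace",
    "TitrationSeries",
    "FitResult",
    "bound_fraction",
    "fit_exponential",
    "relative_activity",
    "fit_kd",
    "dilution_series",
]


@dataclasses.dataclass
class ExchangeTrace:
    time: np.ndarray      # seconds, strictly increasing
    signal: np.ndarray    # fluorescence, arbitrary units

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 5 or self.time.shape != self.signal.shape:
            raise ValueError("need >= 5 matching (time, signal) points")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("times must be strictly increasing")


@dataclasses.dataclass
class TitrationSeries:
    ligand_concentration: np.ndarray   # molar
    response: np.ndarray               # normalised signal
    receptor_concentration: float = 50e-9

    def __post_init__(self) -> None:
        self.ligand_concentration = np.asarray(self.ligand_concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.ligand_concentration.size < 6:
            raise ValueError("need >= 6 titration points")
        if self.ligand_concentration.shape != self.response.shape:
            raise ValueError("concentration and response lengths differ")
        if np.any(self.ligand_concentration <= 0) or self.receptor_concentration <= 0:
            raise ValueError("concentrations must be positive")


@dataclasses.dataclass
class FitResult:
    parameters: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    message: str = ""


def dilution_series(start: float, factor: float = 2.0, n: int = 16) -> np.ndarray:
    """Serial dilution: [start, start/factor, ..., start/factor**(n-1)]."""
    if start <= 0 or factor <= 1 or n < 1:
        raise ValueError("need start > 0, factor > 1, n >= 1")
    return start / factor ** np.arange(n)


def bound_fraction(L: np.ndarray, kd: float, receptor: float) -> np.ndarray:
    """Exact 1:1 bound fraction of receptor at total ligand L.

    Solves the quadratic mass balance for the complex; written in the
    cancellation-free form 2L / (b + sqrt(b^2 - 4 L R)) with
    b = L + R + Kd, which tends to L/(Kd + L) as R -> 0.
    """
    L = np.asarray(L, dtype=float)
    b = L + receptor + kd
    disc = np.sqrt(np.maximum(b * b - 4.0 * L * receptor, 0.0))
    return 2.0 * L / (b + disc)


def _gauss_newton_se(res: np.ndarray, jac: np.ndarray) -> np.ndarray:
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(res @ res) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def fit_exponential(trace: ExchangeTrace, n_starts: int = 5) -> FitResult:
    """Least-squares single-exponential decay fit.

    Starting values come from a log-linearised fit of the baseline-
    subtracted signal; the rate is multi-started over a log-spaced grid
    around it. A trace without a resolvable decaying amplitude returns a
    flagged (non-converged) result rather than raising.
    """
    t, y = trace.time, trace.signal
    y0_init, yinf_init = float(y[0]), float(y.min())
    amp = y0_init - yinf_init
    scale = float(np.ptp(y))
    if scale <= 0 or amp <= 0:
        return FitResult({"k": np.nan, "y0": y0_init, "yinf": yinf_init},
                         {}, rss=float(np.sum((y - y.mean()) ** 2)),
                         converged=False, message="no decaying amplitude")
    # log-linear initial rate from the upper part of the decay
    shifted = y - yinf_init + 1e-12 * scale
    mask = shifted > 0.05 * amp
    k_init = 1.0 / max(t[-1] - t[0], 1e-12)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(shifted[mask]), 1)[0]
        if slope < 0:
            k_init = -slope

    def residuals(p: np.ndarray) -> np.ndarray:
        yinf, a, logk = p
        return yinf + a * np.exp(-np.exp(logk) * t) - y

    best = None
    for k0 in np.exp(np.linspace(np.log(k_init) - 2, np.log(k_init) + 2, n_starts)):
        sol = least_squares(residuals, x0=[yinf_init, amp, np.log(k0)], method="lm",
                            max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    yinf, a, logk = best.x
    k = float(np.exp(logk))
    se = _gauss_newton_se(best.fun, best.jac)
    # delta method: se(k) = k * se(log k)
    stderr = {"yinf": float(se[0]), "amplitude": float(se[1]), "k": k * float(se[2])}
    converged = bool(best.success) and a > 1e-8 * scale and k > 0
    return FitResult(parameters={"k": k, "y0": float(yinf + a), "yinf": float(yinf),
                                 "amplitude": float(a)},
                     stderr=stderr, rss=float(2 * best.cost), converged=converged,
                     message="" if converged else "amplitude not resolved")


def relative_activity(k_variant: float, k_reference: float,
                      se_variant: float = 0.0, se_reference: float = 0.0) -> tuple[float, float]:
    """Rate ratio k_variant / k_reference with quadrature-propagated SE."""
    if k_variant <= 0 or k_reference <= 0:
        raise ValueError("rates must be positive")
    ratio = k_variant / k_reference
    se = ratio * np.sqrt((se_variant / k_variant) ** 2 + (se_reference / k_reference) ** 2)
    return float(ratio), float(se)


def fit_kd(series: TitrationSeries, n_starts: int = 5) -> FitResult:
    """1:1 dissociation-constant fit of a titration series.

    Model: response = U + (B - U) * fb(L; Kd, R) with fb the exact
    quadratic bound fraction. U (unbound plateau), B (bound plateau) and
    Kd are fitted by least squares, multi-started over log-spaced Kd values
    spanning the concentration range. A Kd landing outside
    [min conc / 100, max conc * 100] is flagged as poorly determined.
    """
    L, y, R = series.ligand_concentration, series.response, series.receptor_concentration
    lo, hi = float(L.min()), float(L.max())
    if hi / lo < 100:
        raise ValueError("ligand range must span >= 2 orders of magnitude")

    def residuals(p: np.ndarray) -> np.ndarray:
        U, B, logkd = p
        return U + (B - U) * bound_fraction(L, np.exp(logkd), R) - y

    U0 = float(y[np.argmin(L)])
    B0 = float(y[np.argmax(L)])
    best = None
    for kd0 in np.exp(np.linspace(np.log(lo), np.log(hi), n_starts)):
        sol = least_squares(residuals, x0=[U0, B0, np.log(kd0)], method="lm",
                            max_nfev=10000)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    U, B, logkd = best.x
    kd = float(np.exp(logkd))
    se = _gauss_newton_se(best.fun, best.jac)
    stderr = {"unbound": float(se[0]), "bound": float(se[1]), "kd": kd * float(se[2])}
    in_range = lo / 100 <= kd <= hi * 100
    return FitResult(parameters={"kd": kd, "unbound": float(U), "bound": float(B)},
                     stderr=stderr, rss=float(2 * best.cost),
                     converged=bool(best.success) and in_range,
                     message="" if in_range else "Kd outside supported concentration range")
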