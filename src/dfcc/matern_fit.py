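"""Whittle-Matern regression of correlation-versus-distance curves.

The isotropic Whittle-Matern correlation model

    r(rho) = 2^(1-nu) / Gamma(nu) * (rho/rho_c)^nu * K_nu(rho/rho_c)

has two parameters: the correlation length rho_c (the characteristic
distance over which correlation decays) and the smoothness nu (nu = 1/2
gives the exponential model exp(-rho/rho_c); nu -> infinity approaches the
Gaussian form exp(-rho^2 / (2 rho_c^2))).  K_nu is the modified Bessel
function of the second kind.  The model equals 1 in the rho -> 0 limit and
decreases monotonically to 0.

Fitting is weighted nonlinear least squares with multi-start
initialization over nu; the nu-dependent prefactor is evaluated in log
space so large nu neither overflows Gamma nor underflows the power term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special

from dfcc.spatial_correlation import CorrelationCurve

__all__ = ["MaternFit", "matern_model", "fit_whittle_matern", "fit_all_lags"]

_NU_STARTS = (0.5, 1.0, 2.0)
_NU_BOUNDS = (0.01, 50.0)


@dataclass
class MaternFit:
    """Fitted correlation length and smoothness for one curve."""

    rho_c: float
    nu: float
    residual: float
    converged: bool
    time_lag: int = 1
    kind: str = ""
    n_bins: int = 0

    def __call__(self, rho: np.ndarray) -> np.ndarray:
        return matern_model(rho, self.rho_c, self.nu)

    def effective_range(self, level: float = float(np.exp(-1))) -> float:
        """Distance at which the fitted model decays to ``level``.

        The practical range: unlike rho_c itself, it is comparable across
        fits with different smoothness nu (for small nu the model drops
        steeply well before rho_c; for large nu well after).
        """
        if not (0 < level < 1):
            raise ValueError("level must be in (0, 1)")
        hi = self.rho_c
        while matern_model(hi, self.rho_c, self.nu) > level:
            hi *= 2.0
        return float(
            optimize.brentq(
                lambda r: matern_model(r, self.rho_c, self.nu) - level,
                1e-12 * self.rho_c,
                hi,
            )
        )


def matern_model(rho, rho_c: float, nu: float):
    """Evaluate the Whittle-Matern correlation at distance(s) ``rho``.

    ``rho_c`` and ``nu`` must be positive; ``rho >= 0``.  The removable
    singularity at rho = 0 is filled with its limit value 1.
    """
    if not (rho_c > 0):
        raise ValueError("rho_c must be positive")
    if not (nu > 0):
        raise ValueError("nu must be positive")
    rho = np.asarray(rho, dtype=np.float64)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    scalar = rho.ndim == 0
    x = np.atleast_1d(rho) / rho_c
    out = np.ones_like(x)
    pos = x > 0
    xp = x[pos]
    # log[2^(1-nu)/Gamma(nu) * x^nu * K_nu(x)]; kve = exp(x) K_nu(x) avoids
    # evaluating the huge K_nu and tiny x^nu separately at large nu.
    with np.errstate(over="ignore", divide="ignore"):
        log_val = (
            (1.0 - nu) * np.log(2.0)
            - special.gammaln(nu)
            + nu * np.log(xp)
            + np.log(special.kve(nu, xp))
            - xp
        )
    out[pos] = np.exp(log_val)
    # Round-off near x=0 can push the value epsilon above the limit 1.
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out.reshape(rho.shape)


def _initial_rho_c(rho: np.ndarray, r: np.ndarray) -> float:
    """First distance at which the curve drops below 1/e (fallback: midrange)."""
    below = np.where(r < np.exp(-1.0))[0]
    if below.size and rho[below[0]] > 0:
        return float(rho[below[0]])
    return float(max(rho.max() / 2.0, rho[rho > 0].min() if np.any(rho > 0) else 1.0))


def fit_whittle_matern(
    curve: CorrelationCurve,
    weights: str | np.ndarray | None = "counts",
    min_pairs: int = 100,
    exclude_zero: bool = True,
) -> MaternFit:
    """Weighted least-squares fit of (rho_c, nu) to a correlation curve.

    The rho = 0 bin (trivially 1) is excluded by default, as are bins whose
    pair count falls below ``min_pairs`` — sparsely populated tails
    destabilize nu.  ``weights``: per-bin pair counts (default), an
    explicit array, or None for unweighted.  Bounds: rho_c in
    (0, 10 * rho_max], nu in (0.01, 50].  Deterministic: the multi-start
    grid over nu is fixed.
    """
    rho = np.asarray(curve.rho_px, dtype=np.float64)
    r = np.asarray(curve.r, dtype=np.float64)
    counts = np.asarray(curve.counts, dtype=np.float64)

    keep = np.isfinite(r) & np.isfinite(rho)
    if exclude_zero:
        keep &= rho > 0
    if min_pairs > 0:
        keep &= counts >= min_pairs
    rho_f, r_f, cnt_f = rho[keep], r[keep], counts[keep]
    if rho_f.size < 5:
        raise ValueError(
            f"need at least 5 usable bins to fit, have {rho_f.size} "
            f"(min_pairs={min_pairs})"
        )
    if weights is None:
        w = np.ones_like(rho_f)
    elif isinstance(weights, str) and weights == "counts":
        w = cnt_f / cnt_f.max()
    else:
        w = np.asarray(weights, dtype=np.float64)[keep]
    sqrt_w = np.sqrt(w)

    rho_max = rho_f.max()
    lower = [1e-6 * rho_max, _NU_BOUNDS[0]]
    upper = [10.0 * rho_max, _NU_BOUNDS[1]]
    rc0 = min(max(_initial_rho_c(rho_f, r_f), lower[0] * 1.01), upper[0] * 0.99)

    def residuals(theta):
        return sqrt_w * (r_f - matern_model(rho_f, theta[0], theta[1]))

    best = None
    for nu0 in _NU_STARTS:
        try:
            res = optimize.least_squares(
                residuals, x0=[rc0, nu0], bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return MaternFit(rho_c=np.nan, nu=np.nan, residual=np.inf, converged=False,
                         time_lag=curve.time_lag, kind=curve.kind, n_bins=int(rho_f.size))
    residual = float(np.sqrt(2.0 * best.cost))
    converged = bool(best.status > 0 and np.all(np.isfinite(best.x)))
    return MaternFit(
        rho_c=float(best.x[0]),
        nu=float(best.x[1]),
        residual=residual,
        converged=converged,
        time_lag=curve.time_lag,
        kind=curve.kind,
        n_bins=int(rho_f.size),
    )


def fit_all_lags(
    curves: Mapping[int, object],
    frame_interval_s: float | None = None,
    pixel_size_nm: float | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every (time lag, quantity) curve and tabulate the results.

    ``curves`` maps time lag to either a single :class:`CorrelationCurve`
    or a (direction, magnitude) tuple as produced by
    ``correlation_by_time_lag`` (magnitude may be None).  Per-curve fit
    failures are recorded as non-converged rows rather than aborting.
    """
    if not curves:
        raise ValueError("empty curve map")
    rows = []
    for lag in sorted(curves):
        entry = curves[lag]
        if isinstance(entry, CorrelationCurve):
            entry = (entry,)
        for curve in entry:
            if curve is None:
                continue
            quantity = curve.kind or "direction"
            try:
                fit = fit_whittle_matern(curve, **fit_kwargs)
            except ValueError:
                fit = MaternFit(np.nan, np.nan, np.inf, False, time_lag=lag,
                                kind=quantity)
            row = {
                "time_lag": lag,
                "quantity": quantity,
                "rho_c_px": fit.rho_c,
                "nu": fit.nu,
                "residual": fit.residual,
                "converged": fit.converged,
                "n_bins": fit.n_bins,
            }
            if frame_interval_s is not None:
                row["time_lag_s"] = lag * frame_interval_s
            if pixel_size_nm is not None:
                row["rho_c_nm"] = fit.rho_c * pixel_size_nm
            rows.append(row)
    return pd.DataFrame(rows)
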