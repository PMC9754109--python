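"""Spatial autocorrelation of flow-field direction and magnitude.

Direction is a circular quantity: the angle gamma of each displacement
vector is embedded on the unit circle as exp(i*gamma), so that two vectors
pointing almost along the negative x-axis, at angles pi-eps and -pi+eps,
differ by 2*eps rather than 2*pi-2*eps.  The spatial autocorrelation is
then the mean cosine of the angle difference over all pixel pairs at each
signed lag (dx, dy), computed with zero-padded FFTs and a validity mask so
that undefined angles (zero vectors, pixels outside the nucleus) are
excluded with per-lag pair-count renormalization.

Magnitude m = sqrt(u^2 + v^2) uses the analogous Pearson-style
autocorrelation: mean-subtracted, variance-normalized, same masking.

The 2D correlation surface is finally projected onto the scalar space lag
rho = sqrt(dx^2 + dy^2) by count-weighted radial binning, giving one
correlation-versus-distance curve per time lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import fft as sp_fft

from dfcc.optical_flow import FlowField

__all__ = [
    "AngleField",
    "Correlation2D",
    "CorrelationCurve",
    "ZeroVarianceError",
    "angles_from_flow",
    "circular_autocorrelation",
    "magnitude_autocorrelation",
    "radial_project",
    "correlation_by_time_lag",
]


class ZeroVarianceError(ValueError):
    """Raised when a magnitude field has no variance (correlation undefined)."""


@dataclass
class AngleField:
    """Per-pixel flow direction gamma in (-pi, pi]; NaN marks undefined entries.

    An entry is undefined exactly where the flow vector is (0, 0).
    """

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        defined = np.isfinite(self.gamma)
        vals = self.gamma[defined]
        if np.any(vals <= -np.pi - 1e-12) or np.any(vals > np.pi + 1e-12):
            raise ValueError("defined angles must lie in (-pi, pi]")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.gamma)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


@dataclass
class Correlation2D:
    """Autocorrelation r(dx, dy) over signed space lags, with pair counts.

    ``r`` has shape (2H-1, 2W-1); ``lags_y``/``lags_x`` give the signed lag
    for each row/column.  ``counts`` holds the number of valid pixel pairs
    that entered each lag; lags with no valid pair are NaN in ``r``.
    """

    r: np.ndarray
    counts: np.ndarray
    lags_y: np.ndarray
    lags_x: np.ndarray
    kind: str = ""

    @property
    def origin(self) -> tuple[int, int]:
        return int(np.where(self.lags_y == 0)[0][0]), int(np.where(self.lags_x == 0)[0][0])


@dataclass
class CorrelationCurve:
    """Radial correlation profile r(rho) for one time lag.

    ``rho_px`` are strictly increasing bin centres (px); ``counts`` are the
    summed pair counts per bin.  ``r[0]`` is exactly 1 (the zero-lag bin).
    """

    rho_px: np.ndarray
    r: np.ndarray
    counts: np.ndarray
    time_lag: int = 1
    kind: str = ""

    def rho_nm(self, pixel_size_nm: float) -> np.ndarray:
        return self.rho_px * pixel_size_nm


def angles_from_flow(flow: FlowField) -> AngleField:
    """Direction angle of each displacement vector.

    Implements the full piecewise arctangent case table: gamma = atan2(v, u)
    on (-pi, pi], with gamma = 0 for (u>0, v=0), gamma = pi for (u<0, v=0),
    and an undefined marker (NaN) where u = v = 0.
    """
    u, v = flow.u, flow.v
    gamma = np.arctan2(v, u)
    # atan2(-0.0, u<0) returns -pi; fold onto (-pi, pi].
    gamma = np.where(gamma == -np.pi, np.pi, gamma)
    gamma = np.where((u == 0) & (v == 0), np.nan, gamma)
    return AngleField(gamma)


def _masked_autocorrelation(values: np.ndarray, mask: np.ndarray):
    """Zero-padded (linear) masked autocorrelation via FFT.

    Returns (numerator, counts) arranged on signed lags -(H-1)..(H-1) /
    -(W-1)..(W-1): numerator[dy, dx] = sum over valid pairs of
    values(x, y) * conj(values(x+dx, y+dy)); counts is the number of valid
    pairs per lag.  Linear (non-circular) so opposite image edges are never
    correlated with each other.
    """
    h, w = values.shape
    shape = (sp_fft.next_fast_len(2 * h - 1), sp_fft.next_fast_len(2 * w - 1))
    vm = np.where(mask, values, 0.0)
    fv = sp_fft.fft2(vm, shape)
    fm = sp_fft.fft2(mask.astype(np.float64), shape)
    num = sp_fft.ifft2(fv * np.conj(fv))
    cnt = sp_fft.ifft2(fm * np.conj(fm)).real
    # Re-arrange circular output onto signed lags.
    num = np.roll(num, (h - 1, w - 1), axis=(0, 1))[: 2 * h - 1, : 2 * w - 1]
    cnt = np.roll(cnt, (h - 1, w - 1), axis=(0, 1))[: 2 * h - 1, : 2 * w - 1]
    cnt = np.rint(cnt)
    return num, cnt


def _finalize(num: np.ndarray, cnt: np.ndarray, h: int, w: int, kind: str) -> Correlation2D:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(cnt > 0, num.real / np.maximum(cnt, 1), np.nan)
    origin = (h - 1, w - 1)
    r = r / r[origin]  # exact r(0,0) = 1
    # Autocorrelation symmetry r(dx,dy) = r(-dx,-dy); enforce exactly
    # against FFT round-off.
    r = 0.5 * (r + r[::-1, ::-1])
    lags_y = np.arange(-(h - 1), h)
    lags_x = np.arange(-(w - 1), w)
    return Correlation2D(r=r, counts=cnt, lags_y=lags_y, lags_x=lags_x, kind=kind)


def circular_autocorrelation(angles: AngleField) -> Correlation2D:
    """Circular spatial autocorrelation of a direction field.

    Angles are mapped to unit complex numbers e^{i*gamma}; the forward FFT
    is multiplied by its complex conjugate and inverse-transformed, and the
    real part of the normalized result equals the mean of
    cos(gamma(x, y) - gamma(x+dx, y+dy)) over valid pixel pairs at each lag.
    """
    mask = angles.defined
    if not mask.any():
        raise ValueError("angle field has no defined entries")
    z = np.where(mask, np.exp(1j * np.nan_to_num(angles.gamma)), 0.0)
    num, cnt = _masked_autocorrelation(z, mask)
    h, w = angles.gamma.shape
    return _finalize(num, cnt, h, w, kind="direction")


def magnitude_autocorrelation(
    flow: FlowField, mask: np.ndarray | None = None
) -> Correlation2D:
    """Pearson-style spatial autocorrelation of the displacement magnitude.

    The magnitude field is mean-subtracted and variance-normalized over the
    valid pixels; a zero-variance field has no defined correlation and
    raises :class:`ZeroVarianceError`.
    """
    m = flow.magnitude
    if mask is None:
        mask = np.ones(m.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask excludes every pixel")
    mu = m[mask].mean()
    if np.allclose(m[mask], mu):
        raise ZeroVarianceError("magnitude field has zero variance")
    num, cnt = _masked_autocorrelation(m - mu, mask)
    h, w = m.shape
    return _finalize(num, cnt, h, w, kind="magnitude")


def radial_project(
    corr: Correlation2D, bin_width: float = 1.0, max_lag: float | None = None
) -> CorrelationCurve:
    """Project a 2D correlation surface onto the scalar space lag rho.

    Each signed lag (dx, dy) is assigned to the radial bin whose centre
    k*bin_width is nearest to rho = sqrt(dx^2 + dy^2); the bin value is the
    pair-count-weighted mean of r.  ``max_lag`` defaults to half the
    smaller field dimension, beyond which pair counts are unreliably low.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ly, lx = np.meshgrid(corr.lags_y, corr.lags_x, indexing="ij")
    rho = np.hypot(lx, ly)
    if max_lag is None:
        h = (corr.r.shape[0] + 1) // 2
        w = (corr.r.shape[1] + 1) // 2
        max_lag = min(h, w) / 2.0
    valid = (corr.counts > 0) & np.isfinite(corr.r) & (rho <= max_lag + bin_width / 2)
    idx = np.rint(rho[valid] / bin_width).astype(int)
    wgt = corr.counts[valid]
    val = corr.r[valid]
    n_bins = idx.max() + 1
    sum_w = np.bincount(idx, weights=wgt, minlength=n_bins)
    sum_wr = np.bincount(idx, weights=wgt * val, minlength=n_bins)
    keep = sum_w > 0
    centres = np.arange(n_bins) * bin_width
    r = np.full(n_bins, np.nan)
    r[keep] = sum_wr[keep] / sum_w[keep]
    return CorrelationCurve(
        rho_px=centres[keep], r=r[keep], counts=sum_w[keep], kind=corr.kind
    )


def _combine(surfaces: list[Correlation2D]) -> Correlation2D:
    """Pair-count-weighted average of per-pair correlation surfaces."""
    cnt = np.zeros_like(surfaces[0].counts)
    acc = np.zeros_like(surfaces[0].r)
    for s in surfaces:
        good = s.counts > 0
        acc[good] += s.r[good] * s.counts[good]
        cnt += s.counts
    with np.errstate(invalid="ignore"):
        r = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    first = surfaces[0]
    return Correlation2D(r=r, counts=cnt, lags_y=first.lags_y, lags_x=first.lags_x,
                         kind=first.kind)


def correlation_by_time_lag(
    fields: Sequence[FlowField] | Mapping[int, Sequence[FlowField]],
    lags: set[int] | None = None,
    bin_width: float = 1.0,
    max_lag: float | None = None,
) -> dict[int, tuple[CorrelationCurve, CorrelationCurve | None]]:
    """Direction and magnitude correlation curves per time lag.

    ``fields`` is either a flat list of flow fields (grouped by their
    ``frame_pair`` lag) or a mapping lag -> fields.  For each requested
    time lag, per-pair 2D correlation surfaces are averaged with pair-count
    weights before radial projection.  The magnitude curve is None when
    every field at that lag has zero magnitude variance; the direction
    curve is None when every field is identically zero (no defined angle).
    """
    if isinstance(fields, Mapping):
        grouped: dict[int, list[FlowField]] = {k: list(v) for k, v in fields.items()}
    else:
        grouped = {}
        for f in fields:
            grouped.setdefault(f.time_lag, []).append(f)
    if lags is not None:
        if len(lags) == 0:
            raise ValueError("empty set of time lags")
        missing = set(lags) - set(grouped)
        if missing:
            raise ValueError(f"no flow fields for requested lags {sorted(missing)}")
        grouped = {k: grouped[k] for k in lags}
    if not grouped:
        raise ValueError("no flow fields given")

    out: dict[int, tuple[CorrelationCurve | None, CorrelationCurve | None]] = {}
    for lag in sorted(grouped):
        ffs = grouped[lag]
        dir_surfaces = []
        for f in ffs:
            af = angles_from_flow(f)
            if af.defined.any():  # all-zero flow has no direction at all
                dir_surfaces.append(circular_autocorrelation(af))
        if dir_surfaces:
            dir_curve = radial_project(_combine(dir_surfaces), bin_width, max_lag)
            dir_curve.time_lag = lag
        else:
            dir_curve = None
        mag_surfaces = []
        for f in ffs:
            try:
                mag_surfaces.append(magnitude_autocorrelation(f))
            except ZeroVarianceError:
                continue
        if mag_surfaces:
            mag_curve = radial_project(_combine(mag_surfaces), bin_width, max_lag)
            mag_curve.time_lag = lag
        else:
            mag_curve = None
        out[lag] = (dir_curve, mag_curve)
    return out
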