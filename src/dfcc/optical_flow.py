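"""Dense Horn-Schunck optical flow with pyramidal warping and median filtering.

The flow field (u, v) between two frames minimizes the classic
Horn-Schunck energy: a brightness-constancy data term plus alpha^2 times a
smoothness term on the flow gradients.  The solver is coarse-to-fine: the
frame pair is reduced to an image pyramid, and at each level the second
frame is repeatedly warped towards the first by the current flow estimate
and a linearized increment is solved by Jacobi iterations.  After each
warping step both flow components are median-filtered, which suppresses
outliers introduced by the linearization.

Intensities are jointly min-max normalized to [0, 1] before the solve, so
the regularization weight ``alpha`` is on a fixed intensity scale and the
flow is invariant to multiplying both frames by a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = ["FlowField", "HornSchunckParams", "horn_schunck_flow", "flow_sequence"]

# Horn-Schunck weighted-average (approximate Laplacian) kernel.
_HS_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)


@dataclass
class FlowField:
    """Per-pixel displacement between a frame pair.

    ``u`` is the x-displacement (column index increasing rightward) and
    ``v`` the y-displacement (row index increasing downward), in pixels per
    frame pair unless ``units`` says otherwise.
    """

    u: np.ndarray
    v: np.ndarray
    frame_pair: tuple[int, int] = (0, 1)
    units: str = "px"
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow components must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @property
    def time_lag(self) -> int:
        return self.frame_pair[1] - self.frame_pair[0]

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def to_nm(self, pixel_size_nm: float | None = None) -> "FlowField":
        """Convert a pixel-unit flow to nm (exact, reversible scaling)."""
        if self.units == "nm":
            return self
        scale = pixel_size_nm if pixel_size_nm is not None else self.pixel_size_nm
        if scale is None:
            raise ValueError("pixel_size_nm required to convert to nm")
        return FlowField(self.u * scale, self.v * scale, self.frame_pair, "nm", scale)

    def to_px(self) -> "FlowField":
        if self.units == "px":
            return self
        if self.pixel_size_nm is None:
            raise ValueError("pixel_size_nm unknown; cannot convert back to px")
        return FlowField(
            self.u / self.pixel_size_nm,
            self.v / self.pixel_size_nm,
            self.frame_pair,
            "px",
            self.pixel_size_nm,
        )


@dataclass
class HornSchunckParams:
    """Solver settings; defaults are robust for [0, 1]-normalized intensities."""

    alpha: float = 1.0
    n_warps: int = 5
    n_iters: int = 100
    median_radius: int = 2
    n_levels: int = 3
    downscale: float = 0.5
    tol: float = 1e-8

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_warps < 1:
            raise ValueError("n_warps must be >= 1")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if not (0 < self.downscale < 1):
            raise ValueError("downscale must be in (0, 1)")


def _warp(image: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Backward-warp image by flow with bilinear interpolation, edge clamped."""
    h, w = image.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64),
                         indexing="ij")
    coords = np.stack([yy + v, xx + u])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def _gradients(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central-difference spatial gradients averaged over the frame pair."""
    ay, ax = np.gradient(a)
    by, bx = np.gradient(b)
    return 0.5 * (ax + bx), 0.5 * (ay + by), b - a


def _hs_level(
    a: np.ndarray,
    b: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    p: HornSchunckParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Run warping + Jacobi iterations at one pyramid level."""
    size = 2 * p.median_radius + 1
    for _ in range(p.n_warps):
        bw = _warp(b, u, v)
        ix, iy, it = _gradients(a, bw)
        denom = p.alpha**2 + ix * ix + iy * iy
        du = np.zeros_like(u)
        dv = np.zeros_like(v)
        converged = False
        for _ in range(p.n_iters):
            du_bar = ndimage.convolve(du, _HS_KERNEL, mode="reflect")
            dv_bar = ndimage.convolve(dv, _HS_KERNEL, mode="reflect")
            shared = (ix * du_bar + iy * dv_bar + it) / denom
            du_new = du_bar - ix * shared
            dv_new = dv_bar - iy * shared
            delta = max(np.abs(du_new - du).max(), np.abs(dv_new - dv).max())
            du, dv = du_new, dv_new
            if delta < p.tol:
                converged = True
                break
        if not converged and p.tol > 0 and delta > 1e-3:
            warnings.warn(
                f"Horn-Schunck inner loop not converged (last update {delta:.2e}); "
                "returning best iterate",
                RuntimeWarning,
                stacklevel=3,
            )
        u = u + du
        v = v + dv
        if p.median_radius > 0:
            u = ndimage.median_filter(u, size=size, mode="reflect")
            v = ndimage.median_filter(v, size=size, mode="reflect")
    return u, v


def horn_schunck_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    params: HornSchunckParams | None = None,
    frame_pair: tuple[int, int] = (0, 1),
    **kwargs,
) -> FlowField:
    """Estimate the dense displacement field carrying ``frame_a`` to ``frame_b``.

    Parameters may be given as a :class:`HornSchunckParams` or as keyword
    overrides (``alpha``, ``n_warps``, ``n_iters``, ``median_radius``,
    ``n_levels``, ``downscale``).  Deterministic for fixed inputs.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("frames must be 2D")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("frames must be finite")
    if params is None:
        params = HornSchunckParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword overrides, not both")
    params.validate()

    # Joint normalization: flow invariant to a common intensity scale.
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi > lo:
        a = (a - lo) / (hi - lo)
        b = (b - lo) / (hi - lo)
    else:
        a = np.zeros_like(a)
        b = np.zeros_like(b)

    # Coarse-to-fine pyramid (smallest level first).
    pyramid = [(a, b)]
    for _ in range(params.n_levels - 1):
        pa, pb = pyramid[-1]
        hh = max(8, int(round(pa.shape[0] * params.downscale)))
        ww = max(8, int(round(pa.shape[1] * params.downscale)))
        if hh == pa.shape[0] and ww == pa.shape[1]:
            break
        pyramid.append(
            (
                resize(pa, (hh, ww), anti_aliasing=True, mode="reflect"),
                resize(pb, (hh, ww), anti_aliasing=True, mode="reflect"),
            )
        )
    pyramid.reverse()

    u = np.zeros(pyramid[0][0].shape)
    v = np.zeros(pyramid[0][0].shape)
    for i, (pa, pb) in enumerate(pyramid):
        if u.shape != pa.shape:
            scale_y = pa.shape[0] / u.shape[0]
            scale_x = pa.shape[1] / u.shape[1]
            u = resize(u, pa.shape, mode="edge") * scale_x
            v = resize(v, pa.shape, mode="edge") * scale_y
        u, v = _hs_level(pa, pb, u, v, params)
    return FlowField(u, v, frame_pair=frame_pair)


def flow_sequence(
    seq,
    tau: int = 1,
    params: HornSchunckParams | None = None,
    **kwargs,
) -> list[FlowField]:
    """Flow fields for every frame pair (t, t+tau), t = 0 ... T-tau-1.

    A 150-frame movie at tau=1 yields 149 fields.  Raises if ``tau`` is not
    a valid lag for the sequence length.
    """
    frames = seq.frames if hasattr(seq, "frames") else np.asarray(seq)
    t = frames.shape[0]
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau >= t:
        raise ValueError(f"tau={tau} must be smaller than the number of frames ({t})")
    if params is None:
        params = HornSchunckParams(**kwargs)
    fields = []
    for i in range(t - tau):
        ff = horn_schunck_flow(frames[i], frames[i + tau], params=params,
                               frame_pair=(i, i + tau))
        if hasattr(seq, "pixel_size_nm"):
            ff.pixel_size_nm = seq.pixel_size_nm
        fields.append(ff)
    return fields
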