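"""Synthetic flow fields and image sequences for pipeline validation.

Three generators mirror the validation scenarios used to characterize the
pipeline:

* **Uncorrelated**: each grid point gets an independent displacement with
  magnitude ~ Normal(0.5, 0.05) px (truncated at zero) and direction ~
  Uniform[0, 2*pi).  Measured spatial correlation should be statistical
  noise only.
* **Spatially correlated**: magnitude and/or direction values are derived
  from a stochastic 2D fractal (multifractal-type) random field with a
  power-law spectrum S(k) ~ |k|^-(2H+2); the Hurst exponent H in (0, 1)
  tunes how long-ranged the spatial correlation is.  Alternatively a
  target correlation length can be requested, in which case the underlying
  Gaussian field is synthesized with a Whittle-Matern correlation
  structure calibrated so that the *measured* circular correlation of the
  derived direction field matches the requested Matern curve.
* **Image synthesis**: a smooth random texture advected frame-to-frame by
  a known flow with bilinear warping plus Gaussian read noise, for
  end-to-end tests against ground truth.

Scalar fields are mapped to directions rank-preservingly through the
standard normal CDF, gamma = 2*pi*Phi(z), which makes the marginal
direction distribution exactly uniform; magnitudes use the linear map
m = mean + sd * z (truncated at zero).

All generators are bit-reproducible given (seed, config).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage, special
from scipy.special import ndtr

from dfcc.io_preprocess import ImageSequence
from dfcc.matern_fit import matern_model
from dfcc.optical_flow import FlowField
from dfcc.spatial_correlation import AngleField

__all__ = [
    "SimulationConfig",
    "SyntheticMovie",
    "simulate_flow_field",
    "generate_multifractal_field",
    "generate_matern_field",
    "generate_correlated_direction_field",
    "field_to_direction",
    "field_to_magnitude",
    "synthesize_image_sequence",
    "phase_mapping_transfer",
]

_SCENARIOS = ("none", "magnitude", "direction", "both")


@dataclass
class SimulationConfig:
    """Parameters of one simulated flow-field scenario.

    Defaults are the validation conditions: a 100 x 100 grid, magnitudes
    Normal(0.5, 0.05) px, directions Uniform[0, 2*pi).
    """

    grid_size: int = 100
    magnitude_mean: float = 0.5
    magnitude_sd: float = 0.05
    correlated_quantity: str = "none"
    hurst_exponent: float = 0.5
    target_correlation_length: float | None = None
    matern_nu: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.magnitude_sd < 0:
            raise ValueError("magnitude_sd must be >= 0")
        if self.magnitude_mean <= 0:
            raise ValueError("magnitude_mean must be positive")
        if self.correlated_quantity not in _SCENARIOS:
            raise ValueError(
                f"correlated_quantity must be one of {_SCENARIOS}, "
                f"got {self.correlated_quantity!r}"
            )
        if not (0 < self.hurst_exponent < 1):
            raise ValueError("hurst_exponent must be in (0, 1)")
        if self.target_correlation_length is not None and self.target_correlation_length <= 0:
            raise ValueError("target_correlation_length must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticMovie:
    """A synthetic image sequence together with its ground-truth flow.

    ``flows`` holds one ground-truth field per frame transition;
    ``flow`` is the first of them (convenient for single-flow movies).
    """

    sequence: ImageSequence
    flows: list
    noise_sd: float = 0.0
    seed: int | None = None

    @property
    def flow(self) -> FlowField:
        return self.flows[0]


def generate_multifractal_field(
    grid_size: int, hurst_exponent: float, seed: int | None | np.random.Generator = None
) -> np.ndarray:
    """Fractal random field with power-law spectrum S(k) ~ |k|^-(2H+2).

    Synthesized in Fourier space: complex white noise is shaped by the
    amplitude |k|^-(H+1) with the DC component zeroed, inverse-transformed,
    and standardized to exactly zero mean and unit variance.  Spatial
    correlation range increases with the Hurst exponent H.
    """
    if not (0 < hurst_exponent < 1):
        raise ValueError("hurst_exponent must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = grid_size
    kx = np.fft.fftfreq(n)[None, :]
    ky = np.fft.fftfreq(n)[:, None]
    k = np.hypot(kx, ky)
    with np.errstate(divide="ignore"):
        amplitude = np.where(k > 0, k ** -(hurst_exponent + 1.0), 0.0)
    noise = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    fld = np.real(sp_fft.ifft2(amplitude * noise))
    fld -= fld.mean()
    fld /= fld.std()
    return fld


def _circulant_spectrum(corr_of_rho, grid_size: int) -> tuple[np.ndarray, float]:
    """Spectral factor of a prescribed isotropic correlation on the torus.

    ``corr_of_rho`` maps distance (px) to correlation in [0, 1].  Negative
    spectral components arising from the torus embedding are clipped to
    zero, the usual approximation when the correlation range is well below
    the grid size.  Returns the clipped spectrum and the exact ensemble
    variance of fields sampled from it.
    """
    n = grid_size
    idx = np.minimum(np.arange(n), n - np.arange(n)).astype(np.float64)
    rho = np.hypot(idx[:, None], idx[None, :])
    cov = corr_of_rho(rho)
    spectrum = np.clip(np.real(sp_fft.fft2(cov)), 0.0, None)
    var = float(np.real(sp_fft.ifft2(spectrum))[0, 0])
    if var <= 0:
        raise ValueError("degenerate correlation surface")
    return spectrum, var


def _sample_field(spectrum: np.ndarray, var: float, rng: np.random.Generator) -> np.ndarray:
    """One zero-mean, unit-variance Gaussian field from a circulant spectrum.

    Normalized by the deterministic ensemble variance, not the sample
    moments: per-realization standardization would bias the long-range
    correlation downward on windows comparable to the correlation range.
    """
    n = spectrum.shape[0]
    noise = rng.normal(size=(n, n))
    fld = np.real(sp_fft.ifft2(np.sqrt(spectrum) * sp_fft.fft2(noise)))
    return fld / np.sqrt(var)


def _circulant_gaussian_field(
    corr_of_rho, grid_size: int, rng: np.random.Generator
) -> np.ndarray:
    spectrum, var = _circulant_spectrum(corr_of_rho, grid_size)
    return _sample_field(spectrum, var, rng)


def phase_mapping_transfer(c):
    """Circular correlation of the two-field phase mapping.

    If (z1, z2) and (z1', z2') are pairs of standard Gaussian fields with
    cross-realization correlation c, the directions gamma = atan2(z2, z1)
    satisfy E[cos(gamma - gamma')] = (pi/4) * c * 2F1(1/2, 1/2; 2; c^2).
    Monotone from 0 to 1 on c in [0, 1]; the attenuation (g(c) <= c) is
    what a correlation-targeted direction field must pre-compensate.
    """
    c = np.clip(np.asarray(c, dtype=np.float64), -1.0, 1.0)
    return (np.pi / 4.0) * c * special.hyp2f1(0.5, 0.5, 2.0, c * c)


_PHASE_INVERSE_GRID = None


def _invert_phase_transfer(r: np.ndarray) -> np.ndarray:
    """c = g^{-1}(r) for the phase-mapping transfer, by monotone interpolation."""
    global _PHASE_INVERSE_GRID
    if _PHASE_INVERSE_GRID is None:
        c_grid = np.linspace(0.0, 1.0, 4001)
        _PHASE_INVERSE_GRID = (phase_mapping_transfer(c_grid), c_grid)
    g_vals, c_grid = _PHASE_INVERSE_GRID
    return np.interp(r, g_vals, c_grid)


def generate_matern_field(
    grid_size: int,
    rho_c: float,
    nu: float = 1.0,
    seed: int | None | np.random.Generator = None,
) -> np.ndarray:
    """Gaussian field whose spatial correlation follows a Whittle-Matern curve."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _circulant_gaussian_field(
        lambda rho: matern_model(rho, rho_c, nu), grid_size, rng
    )


def generate_correlated_direction_field(
    grid_size: int,
    rho_c: float,
    nu: float = 1.0,
    seed: int | None | np.random.Generator = None,
) -> AngleField:
    """Direction field whose circular correlation matches Matern(rho_c, nu).

    Two independent Gaussian fields (z1, z2) are synthesized with the
    pre-distorted correlation g^{-1}(Matern) — g being
    :func:`phase_mapping_transfer` — and the direction is their phase,
    gamma = atan2(z2, z1).  The phase is invariant to the fields' local
    amplitude, so the measured circular correlation tracks the target
    curve without sensitivity to per-realization variance fluctuations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spectrum, var = _circulant_spectrum(
        lambda rho: _invert_phase_transfer(matern_model(rho, rho_c, nu)), grid_size
    )
    z1 = _sample_field(spectrum, var, rng)
    z2 = _sample_field(spectrum, var, rng)
    gamma = np.arctan2(z2, z1)
    gamma = np.where(gamma == -np.pi, np.pi, gamma)
    return AngleField(gamma)


def field_to_direction(field: np.ndarray) -> AngleField:
    """Map a standardized scalar field to directions, gamma = 2*pi*Phi(z).

    Rank-preserving and marginally uniform on the circle (Phi is the
    standard normal CDF).  Angles are folded onto (-pi, pi]; the raw
    [0, 2*pi) value is recovered as ``mod(gamma, 2*pi)``.
    """
    gamma = 2.0 * np.pi * ndtr(np.asarray(field, dtype=np.float64))
    gamma = np.mod(gamma, 2.0 * np.pi)
    gamma = np.where(gamma > np.pi, gamma - 2.0 * np.pi, gamma)
    return AngleField(gamma)


def field_to_magnitude(field: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map a standardized scalar field to magnitudes, m = mean + sd * z.

    Marginally Normal(mean, sd), truncated at zero (with mean 0.5 and sd
    0.05 the truncation is a 10-sigma event, statistically negligible).
    """
    m = mean + sd * np.asarray(field, dtype=np.float64)
    return np.clip(m, 0.0, None)


def _iid_truncated_normal(
    shape, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(shape, float(mean))
    m = rng.normal(mean, sd, size=shape)
    bad = m < 0
    while bad.any():  # resample negatives; vanishing probability at 10 sigma
        m[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = m < 0
    return m


def simulate_flow_field(config: SimulationConfig) -> FlowField:
    """Draw one flow field according to the configured scenario.

    Uncorrelated quantities are i.i.d. (magnitude truncated normal,
    direction uniform on the circle); correlated quantities are derived
    from independent spatial random fields — Matern-structured when a
    target correlation length is set, power-law (Hurst) otherwise.  The
    components are u = m cos(gamma), v = m sin(gamma).
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.grid_size
    corr_dir = config.correlated_quantity in ("direction", "both")
    corr_mag = config.correlated_quantity in ("magnitude", "both")

    targeted = config.target_correlation_length is not None

    if corr_dir:
        if targeted:
            gamma = generate_correlated_direction_field(
                n, config.target_correlation_length, config.matern_nu, seed=rng
            ).gamma
        else:
            gamma = field_to_direction(
                generate_multifractal_field(n, config.hurst_exponent, seed=rng)
            ).gamma
    else:
        gamma = rng.uniform(0.0, 2.0 * np.pi, size=(n, n))
    if corr_mag:
        if targeted:
            fld = generate_matern_field(
                n, config.target_correlation_length, config.matern_nu, seed=rng
            )
        else:
            fld = generate_multifractal_field(n, config.hurst_exponent, seed=rng)
        m = field_to_magnitude(fld, config.magnitude_mean, config.magnitude_sd)
    else:
        m = _iid_truncated_normal((n, n), config.magnitude_mean, config.magnitude_sd, rng)

    return FlowField(u=m * np.cos(gamma), v=m * np.sin(gamma))


def synthesize_image_sequence(
    flow: FlowField | list[FlowField],
    n_frames: int = 10,
    texture_sigma: float = 2.0,
    noise_sd: float = 0.005,
    seed: int | None = None,
    pixel_size_nm: float = 65.0,
    frame_interval_s: float = 0.2,
) -> SyntheticMovie:
    """Advect a smooth random texture by known flow, frame to frame.

    ``flow`` is either a single field applied at every transition or a
    family (list) with one field per transition, in which case
    ``n_frames = len(flow) + 1``.  Frame t+1 is the bilinear backward warp
    of frame t by the flow (``I[t+1](x) = I[t](x - u(x))``), plus i.i.d.
    Gaussian read noise of standard deviation ``noise_sd`` on the [0.1, 1]
    intensity scale.  Ground-truth flows are returned alongside the
    sequence.
    """
    if isinstance(flow, FlowField):
        if n_frames < 2:
            raise ValueError("need at least 2 frames")
        flows = [flow] * (n_frames - 1)
    else:
        flows = list(flow)
        if not flows:
            raise ValueError("flow family is empty")
        n_frames = len(flows) + 1
    h, w = flows[0].shape
    max_disp = max(f.magnitude.max() for f in flows)
    if max_disp > min(h, w) / 3.0:
        warnings.warn(
            f"maximum displacement {max_disp:.1f} px exceeds a third of the grid; "
            "flow recovery will be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.normal(size=(h, w)), texture_sigma, mode="wrap")
    texture -= texture.min()
    peak = texture.max()
    if peak > 0:
        texture /= peak
    texture = 0.1 + 0.9 * texture

    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    frames = [texture]
    for i, f in enumerate(flows):
        coords = np.stack([yy - f.v, xx - f.u])
        frames.append(ndimage.map_coordinates(frames[-1], coords, order=1, mode="reflect"))
        flows[i] = FlowField(f.u, f.v, frame_pair=(i, i + 1), units=f.units,
                             pixel_size_nm=f.pixel_size_nm)
    stack = np.stack(frames)
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None)
    seq = ImageSequence(stack, pixel_size_nm, frame_interval_s, label="synthetic")
    return SyntheticMovie(sequence=seq, flows=flows, noise_sd=noise_sd, seed=seed)


def direction_quantile(z: np.ndarray) -> np.ndarray:
    """Inverse helper for tests: raw [0, 2*pi) direction values of a field."""
    return 2.0 * np.pi * ndtr(np.asarray(z, dtype=np.float64))
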