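# dfcc — dense flow reconstruction and correlation

`dfcc` quantifies **spatially coherent motion across an entire cell nucleus**
from 2D live-cell fluorescence image sequences (chromatin stains, RNA Pol II
fusions, or any dense nuclear signal). Instead of tracking individual
particles, it reconstructs a dense displacement field for every pixel and
every frame pair, and then asks over what distance neighbouring displacement
vectors stay correlated — the signature of chromatin moving as coherent
domains rather than independently.

The pipeline:

1. **Preprocessing** — single-pass bilateral denoising (window 5 px,
   σ_space 5 px, σ_intensity 0.3 on [0, 1]-normalized intensities) and
   lateral-drift QC by subpixel phase correlation: recordings drifting more
   than 10 nm are excluded.
2. **Optical flow** — Horn–Schunck variational estimation of the dense
   displacement field (u, v) between frames t and t+τ, with coarse-to-fine
   warping and median filtering of the flow after each warping step.
3. **Spatial correlation** — the flow **direction** γ = atan2(v, u) is
   embedded on the unit circle as e^{iγ}, so two vectors at angles π−ε and
   −π+ε differ by 2ε, not 2π−2ε. Its autocorrelation (the mean cosine of the
   angle difference over all pixel pairs at each lag) and the Pearson-style
   autocorrelation of the **magnitude** m = √(u²+v²) are computed with
   zero-padded FFTs and a validity mask, then projected onto the scalar
   space lag ρ = √(Δx²+Δy²).
4. **Whittle–Matérn regression** — each correlation-versus-distance curve is
   fitted with

   r(ρ) = 2^(1−ν)/Γ(ν) · (ρ/ρ_c)^ν · K_ν(ρ/ρ_c),

   giving a correlation length ρ_c and smoothness ν per time lag (ν = ½ is
   the exponential model, ν → ∞ the Gaussian).
5. **Simulator** — synthetic flow-field scenarios (uncorrelated
   Normal(0.5, 0.05) px magnitudes with uniform directions on a 100-grid;
   spatially correlated directions/magnitudes from fractal or
   Matérn-structured random fields) and image sequences advected by known
   flow, so every stage is validated against ground truth without
   microscope data.

## Worked example

Simulate a direction-correlated flow scenario with a 10 px target
correlation length, advect a texture into a 16-frame movie, and recover the
correlation length through the full pipeline:

```python
import numpy as np
from dfcc import (SimulationConfig, simulate_flow_field, synthesize_image_sequence,
                  flow_sequence, correlation_by_time_lag, fit_all_lags)
from dfcc.optical_flow import HornSchunckParams

rng = np.random.default_rng(0)
flows = [simulate_flow_field(SimulationConfig(
            correlated_quantity="direction", target_correlation_length=10.0,
            rng_seed=int(rng.integers(2**31))))
         for _ in range(15)]
movie = synthesize_image_sequence(flows, seed=1)

estimated = flow_sequence(movie.sequence, tau=1,
                          params=HornSchunckParams(alpha=0.25, median_radius=1))
curves = correlation_by_time_lag(estimated)
table = fit_all_lags(curves, frame_interval_s=0.2, pixel_size_nm=65.0)
print(table[["time_lag_s", "quantity", "rho_c_px", "rho_c_nm", "nu", "converged"]]
      .round(3).to_string(index=False))
```

Output:

```
 time_lag_s  quantity  rho_c_px  rho_c_nm    nu  converged
        0.2 direction    10.214   663.889 0.868       True
        0.2 magnitude     1.301    84.542 2.547       True
```

The direction correlation length comes back at 10.2 px (≈ 664 nm at a 65 nm
pixel) against the 10 px ground truth — the directions were generated
coherent over that scale. The magnitudes were drawn independently per pixel,
so their fitted length stays at the short-range floor left by the flow
estimator's smoothing.

## Command line

```sh
dfcc run movie.tif --tau 1 --out results/        # full analysis of a TIFF recording
dfcc simulate --scenario direction --target-rho-c 10 --seed 1 --out sim/
dfcc qc-drift movie.tif                           # drift estimation + 10 nm rule only
dfcc fit results/curves.csv --out refit.csv       # re-fit saved curves
```

Each run writes curves (`curves.csv`), fits (`fits.csv`), a QC record
(`qc.json`) and a reproducible run record (configuration + version + seed).
Exit codes distinguish success (0), drift-QC rejection (2), fit
non-convergence (3) and input errors (4).

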