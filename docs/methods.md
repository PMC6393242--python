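# Methods note

## Kinetic model

tRNA exchange between nucleus (N) and cytoplasm (C) is modelled as
first-order transport across the nuclear envelope in a closed cell:

```
dC_N/dt = k_in·C_C − k_out·C_N
V_N·C_N(t) + V_C·C̄_C(t) = V_C·C̄_C(0)          (mass conservation)
```

with import and export rate constants `k_in`, `k_out` in min⁻¹ and
concentrations per unit compartment volume. The measured cytoplasmic
signal `C_C` is the perinuclear concentration; the conservation law
involves the cytoplasm-wide mean `C̄_C`. Both compartments are assumed
internally well mixed on the timescale of envelope transport, in the
weak sense that the *shape* of the cytoplasmic spatial profile stays
fixed while its amplitude evolves. Then `C̄_C = w·C_C` with a constant
profile factor `0 < w ≤ 1`, and with φ = V_N/V_C the nuclear-to-
cytoplasmic fluorescence intensity ratio FIR = C_N/C_C after an
all-cytoplasmic bolus at t = 0 has the closed form

```
FIR(t)  = (1 − e^(−t/τ)) / (k_out/k_in + c·e^(−t/τ))
τ       = 1 / (k_out + c·k_in)
FIR_∞   = k_in/k_out
```

where `c = φ/w` is a single composite geometry parameter — φ and w are
not separately identifiable from FIR data. `c` may be supplied
(`c_mode=<float>`) or fitted (`c_mode="free"`). Note τ depends on `c`:
the same rate constants give different relaxation times under
different geometric assumptions, while the plateau `FIR_∞ = k_in/k_out`
does not depend on `c` at all.

Assumptions: membrane-impermeable tracer (closed cell), no synthesis
or degradation over the observation window, first-order fluxes,
constant compartment volumes, fixed cytoplasmic profile shape.

## Time-dependent rates

A `RateSchedule` is a piecewise-linear path in (k_in, k_out); a media
switch is modelled as a linear ramp from one condition's rates to the
other's over a fixed duration (default 25 min). The ODE is integrated
with `scipy.integrate.solve_ivp` (RK45, rtol 1e-8, atol 1e-10),
restarted at every ramp breakpoint so the integrator never steps
across a derivative kink. `C_C` is eliminated algebraically through
the conservation law, so only `C_N` is integrated and mass is
conserved to solver tolerance by construction.

## Fitting

`fit_eq1` minimizes (optionally σ-weighted) residuals of the closed
form with `scipy.optimize.least_squares` (Trust Region Reflective),
bounds k ∈ [0, 10] min⁻¹ and c ∈ [0, 2], default start
(k_in, k_out, c) = (0.2, 0.2, 0.3), plus 5 multiplicatively jittered
restarts keeping the best cost. Standard errors come from the
Gauss–Newton covariance (J'J)⁻¹ scaled by residual variance; SEs for
the derived quantities τ and FIR_∞ use the delta method. Replicate
series may be pooled into a single residual vector. `r_squared` is
relative to the mean-only model and is NaN (with a warning) for
zero-variance data. `bootstrap_ci` resamples residuals (≥100 draws
enforced). `fit_exponential` fits the saturating three-parameter
exponential `A(1 − e^(−t/τ)) + B` with τ parameterized on a log scale
for positivity; it coincides with the kinetic form when c = 0.

Whether `c` should be fixed or free depends on the data: with a single
noiseless series all three parameters are identifiable, but with noisy
short series the (k_in, c) pair is weakly identified and fixing `c`
from independent geometry measurements stabilizes the rate estimates.
The replicate-recovery analysis therefore fixes `c`; the
time-constant recovery fits leave all parameters free.

## Synthetic-cell generator

The generator produces 2-D ground-truth concentration fields for an
elliptical cell with a circular, offset nucleus (default radius 7 μm,
0.2 μm/px, 256×256; tests use 128×128 with semi-axes 11×9 μm). The
cytoplasmic profile shape is one of: flat, monotone exponential decay,
or a peaked perinuclear ring (Gaussian rise to the peak, exponential
decay outside). Fields are scaled so that the image value at
1.5 μm outside the nuclear membrane equals the model's `C_C`,
matching where the quantification samples. `generate_timelapse`
drives the compartment ODE and emits one field per requested time with
exact `w_true` and `fir_true` recorded per frame. `render_frame`
applies optional Gaussian PSF blur, Poisson shot noise at a chosen
photons-per-unit gain, and additive Gaussian read noise; all noise is
drawn from `numpy.random.default_rng` with explicit seeds (per-frame
child seeds < 2³¹ derived from the stack seed). `generate_fir_series`
produces FIR time series directly with lognormal multiplicative noise
`exp(N(0, σ²))`, which keeps values positive and gives symmetric
relative errors.

The generator emulates geometry, compartment kinetics, and camera
statistics only. It does not model optical sectioning in z, spatially
varying background, photobleaching, cell motion, or out-of-focus
light; conclusions about those effects cannot be drawn from it.

## Quantification

FIR is measured from 5×5-pixel ROI boxes: 8 nuclear boxes on a circle
4 px inside the membrane and 8 cytoplasmic boxes at 1.5 μm outside it,
at equal angular spacing; boxes colliding with a mask boundary are
dropped with a warning. Radial intensity profiles average 72 rays from
the nucleus center using bilinear interpolation
(`scipy.ndimage.map_coordinates`), normalized to the first frame's
maximum (the constant is stored so later frames share the scale).
Perinuclear-ring detection (`ring_stats`) uses
`scipy.signal.find_peaks`/`peak_widths` with a prominence threshold of
0.02 on the normalized profile, excluding a 0.5 μm margin around the
nuclear boundary where interpolation across the concentration step
creates spurious extrema. Cell segmentation, when masks are not
supplied, is Otsu thresholding followed by largest-connected-component
selection and hole filling.

## Transport null models

Two cytoplasmic transport nulls are provided. (1) Pure 2-D diffusion:
explicit forward-time centered-space stencil on the cell mask with
zero-flux (mass-conserving) boundaries; the mask is padded by one
pixel so array wraparound cannot couple opposite edges; the time step
is capped at h²/4D. (2) Radial drift–diffusion steady state on the
annulus r_N ≤ r ≤ r_cell with inward drift speed v:
`C(r) ∝ exp(−v·(r − r_N)/D)`, normalized to unit mass using exact
annular areas π(r_{i+1}² − r_i²). An independent finite-volume oracle
(dense flux-balance linear system with a mass-constraint row) checks
the analytic profile; `profile_mismatch` compares a measured radial
profile against either null after least-squares amplitude scaling.

## Numerical choices (summary)

- ODE: RK45, rtol 1e-8 / atol 1e-10, segment-wise at rate breakpoints.
- Optimizer: TRF, bounds k ∈ [0, 10], c ∈ [0, 2], 5 restarts.
- Diffusion stencil: dt ≤ h²/4D, padded zero-flux mask.
- Ring detection: prominence 0.02, nuclear-boundary margin 0.5 μm.
- Profile-factor sanity threshold: warn when measured w > 1.05.
- All randomness: `numpy.random.default_rng` with explicit seeds;
  derived child seeds are reduced below 2³¹.

## Limitations

The model is zero-dimensional per compartment; any genuine
redistribution of the cytoplasmic profile shape over time violates the
constant-w assumption and biases `c`. Fits assume independent,
homoscedastic (or supplied-σ) noise; correlated acquisition noise will
make the reported SEs optimistic. The synthetic generator is 2-D and
noise-model-limited as described above, so recovery results quantify
the measurement chain's algorithmic fidelity, not full experimental
error. The drift–diffusion null treats the cytoplasm as radially
symmetric, which real cells are not.
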