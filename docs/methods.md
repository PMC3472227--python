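# Methods

## Model and assumptions

Wave intensity analysis treats arterial waves as summations of incremental
wavefronts travelling forward (+, away from the heart) and backward (−,
toward the heart) along a vessel. At one measurement site, with velocity *U*
and cross-sectional area *A*:

- Bramwell–Hill: *c² = 1/(ρD) = A dP / (ρ dA)*, with *ρ* the blood density
  and *D* the local distensibility.
- Waterhammer (pressure form): *dP± = ±ρ c dU±*. Substituting eliminates
  *P*: *c = dU/dlnA* for unidirectional wavefronts, and the area-form
  waterhammer is *dU± = ±c·dlnA±*.
- Linearity of superposition: *dU = dU₊ + dU₋*, *dlnA = dlnA₊ + dlnA₋*,
  which with the waterhammer relation gives the closed-form separation
  *dU± = ½(dU ± c·dlnA)*, *dlnA± = ½(dlnA ± dU/c)*.
- Net wave intensity *dI_A = dU·dlnA*; separated intensities
  *dI± = dU±·dlnA± = ±c·(dlnA±)²*, hence the sign laws *dI₊ ≥ 0 ≥ dI₋* and
  exact additivity (the cross terms cancel algebraically).

Assumptions inherited from this formulation: a single scalar wave speed for
the whole cycle at the measurement site; no reflected waves during the
early-systolic window used to estimate *c*; increments (per sampling
interval), not time derivatives, are the working objects, so raw *dI* values
are only comparable at equal sampling intervals. The time-corrected form
*(dU/dt)(dlnA/dt) = dI/dt²* removes the interval dependence when needed.

Working with area rather than diameter makes no circularity assumption, and
working with lnA makes every downstream quantity invariant to the area unit
(*A → kA* shifts lnA additively). Wave speed is likewise invariant to
constant velocity offsets.

## Pipeline and parameters

`analyze()` runs: load/validate → resample to a uniform grid → Savitzky-
Golay smoothing → systolic-foot detection → U–lnA loop → linear-window
selection → wave speed → separation → wave intensity → peak classification.

| parameter | default | meaning |
|---|---|---|
| `dt_ms` | 1.0 | uniform resampling interval [ms]; data are only upsampled |
| `interpolation` | monotone-cubic | shape-preserving PCHIP; `linear` available (the choice is immaterial on smooth physiological waveforms — checked in tests) |
| `sg_poly_order` / `sg_window` | 3 / 101 | Savitzky-Golay order and window [samples]; 101 samples = 100 ms at 1 ms. `None` disables smoothing |
| `smooth_velocity` | False | smooth U with the same filter as A (see "Filtering bias" below) |
| `foot_threshold` | 0.05 | systolic foot = last sample before U exceeds baseline + 5% of the upstroke excursion; baseline is the median of the first 5% of samples |
| `min_window_ms` | 20 | minimum length of the loop's linear window, preventing degenerate near-two-point perfect fits |
| `noise_floor_fraction` | 0.02 | a wave smaller than 2% of the FCW peak is reported absent |
| `rho` | None | blood density [kg/m³]; when given, distensibility 1/(ρc²) [1/Pa] is reported (1060 is the conventional value) |

Numerical choices:

- **Window selection** maximises the R² of U-on-lnA ordinary least squares
  over all contiguous windows within [systolic foot, peak velocity];
  reflections are expected after peak velocity, so the search never extends
  beyond it. The window may start after the foot. R² values within 1e-12 of
  the maximum are treated as tied; ties resolve to the longest window, then
  the earliest start, keeping the selection deterministic on exactly linear
  loops. Both coordinates are centred before the prefix-sum moment
  computation to avoid catastrophic cancellation (lnA ≈ 6.4 with excursions
  of ~0.1).
- **OLS of U on lnA** (not orthogonal regression) follows the loop-gradient
  convention of the pressure–velocity loop literature. No time-alignment
  shift between U and A is applied; the two series come from the same
  acquisition.
- **Smoothing** uses `scipy.signal.savgol_filter(mode="interp")`: each edge
  is handled by the polynomial fitted to the first/last full window. An even
  window has no centred realisation and is rejected; series shorter than the
  window shrink it to the largest valid odd size and record the value used.
  An order-3 filter reproduces cubics exactly and is linear — both are
  asserted in tests.
- **Increments** are backward first differences at the resampled interval.
  Integration constants of the separated curves are assigned wholly to the
  forward components, so the backward curves start at zero — one admissible
  convention, recorded in the output.
- **Peak classification** uses wavefront signs, not fixed time cut-offs:
  FCW is the largest *dI₊* among accelerating forward wavefronts
  (*dU₊ > 0*) from the foot onward; FEW the largest *dI₊* among
  decelerating ones (*dU₊ < 0*) after the FCW; BCW the most negative *dI₋*
  between them. Peak *values* are the sample maxima. Peak *times* are the
  intensity-weighted centroids of each lobe's super-half-maximum region:
  the raw argmax time wanders by more than the sampling interval under
  measurement noise when a lobe is flat-topped, while the centroid of a
  symmetric lobe is unbiased and far more stable (noise-free, the two
  coincide).
- **Degenerate inputs** raise typed errors naming the stage: non-positive
  area (lnA undefined), non-monotone time, flat velocity (no upstroke),
  constant lnA in the fit window (vertical loop), too-short search spans.

### Filtering bias: why the validation harness smooths both signals

Smoothing only the area curve — the display default — filters one of the two
signals whose increment ratio is the estimand. Wherever the filter
attenuates the upstroke, the loop gradient dU/dlnA is inflated by the
attenuation factor. On ground-truth waveforms with a ~120 ms upstroke, a
100 ms window biases the recovered wave speed by roughly +7% even though the
selected window's R² exceeds 0.99999 — the fit quality metric cannot see the
bias. Filtering U and A with the *same* filter cancels the distortion to
first order (measured residual bias ~0.5% noise-free, ~1.5% median under
study noise). The recovery harness (`recovery_experiment`) therefore
analyses noisy data with `smooth_velocity=True`, and noise-free data with
smoothing disabled entirely. The display pipeline keeps the conventional
area-only smoothing; users estimating wave speed quantitatively should
prefer matched filtering, and this is the package's recommendation.

## Synthetic data generator

`generate(SyntheticSpec())` emulates a prospectively gated PC-CMR
acquisition of a healthy-adult ascending aorta over one cardiac cycle:

- Forward wavelets are raised-cosine lobes of velocity rate *dU₊/dt* with
  compact support; each carries a programmed total velocity change. The
  default template has a dominant compression wavelet (centre 100 ms, width
  120 ms, ΔU = 1.0 m/s — a ~1 m/s aortic velocity excursion over a ~120 ms
  acceleration) and a gentler expansion wavelet (centre 290 ms, width
  250 ms, ΔU = −0.85 m/s): aortic deceleration lasts roughly twice as long
  as acceleration, which is why the FEW peak is several-fold smaller than
  the FCW peak in healthy adults.
- The forward log-area follows the waterhammer relation exactly:
  *dlnA₊ = dU₊/c_true* (default c_true = 5.8 m/s, the healthy-adult
  ascending-aortic value; diastolic area 600 mm²).
- The optional reflection is a delayed copy of the forward compression
  wavelet scaled by R (default 0.15, arriving 60 ms later), with
  *dU₋ = −R·dU₊(t−Δ)* and *dlnA₋ = −dU₋/c_true* — a small mid-systolic
  backward compression wave, as seen in central vessels.
- Sampling at the native resolution (default 9.6 ms), truncation to the
  acquired fraction of the cycle (default 85% of an 800 ms cycle: prospective
  gating misses end diastole), then independent additive white Gaussian
  noise on U (0.01 m/s) and A (0.5 mm²).
- `synthesize_pressure` optionally produces the Bramwell–Hill-consistent
  pressure, whose P–U loop gradient equals ρ·c_true — a cross-formulation
  consistency check.

Before noise, the construction satisfies the separation algebra exactly:
separating the generated increments with c_true recovers every component to
machine precision, which is what makes the generator a usable oracle.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: segmentation error structure (correlated,
signal-dependent, occasionally gross), beat-to-beat physiological variation,
baseline drift, partial-volume and blood-signal effects at end systole,
non-Gaussian or heavy-tailed noise, multiple distributed reflection sites,
and any within-cycle variation of the true wave speed. Recovery results here
bound what the pipeline itself contributes to error, not what imaging
contributes.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` use: 1,000 random increment
series for the separation algebra; a 10-value generative sweep (3–12 m/s)
for noise-free exactness; 100 noisy repetitions for Monte-Carlo recovery;
50 random loops (≤ 140 samples) for exhaustive window-selection equivalence;
seeded 15×2 matrices for the ICC/Bland–Altman oracles. These sizes give
stable statistics at interactive runtimes.

## Known limitations

- A single scalar wave speed per cycle; no time-varying or
  frequency-dependent wave speed.
- The linear-window R² criterion can prefer a slightly biased window when a
  filter has distorted one signal (see "Filtering bias") — fit quality is a
  necessary, not sufficient, indicator.
- Prospectively gated inputs are never wrapped; waves arriving after the
  acquired window are simply not seen.
- Raw dI magnitudes depend on the sampling interval as dt²; compare across
  acquisitions only via the time-corrected form.
- The ICC confidence interval uses the standard F-based construction, which
  is approximate for non-normal rating errors.
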