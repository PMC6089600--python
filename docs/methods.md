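# Methods

This note documents the models implemented in `ktflim`, the choices made
where the underlying science left the design open, and what the synthetic
data do and do not establish about real measurements.

## TCSPC decay model and Bayesian inference (`ktflim.flim`)

A recorded decay is a histogram of photon arrival times over `n_bins` coarse
bins, each spanning `adc_ratio` fine bins of width `Δt̃` (the bin width at
which the IRF is measured; defaults 64 × 16 × 12.5 ps = a 12.8 ns window).
The model curve on the fine time base is

    h(k) = IRF ⊛ [A·g(k) + (1 − A)/N_fine],

a circular convolution of the unit-sum IRF with the exponential decay model
`g` plus a time-uniform noise floor of weight `1 − A` (`noise_a` = A ∈ (0,1],
default 1). `g` is either a single exponential at the donor lifetime τ_D or
the two-exponential FRET mixture. Two numerical choices matter:

- **Exact bin masses, window folding.** Rather than sampling the exponential
  at bin centers, each fine bin holds the exact integral of an exponential
  *folded at the measurement window* (the steady state under periodic pulsed
  excitation at high repetition rate). Per-coarse-bin probabilities therefore
  sum to exactly 1, the likelihood is multinomial, and the expected total
  count of a simulated decay equals the photon budget exactly. For a delta
  IRF the per-bin probabilities agree with the continuous-time closed form to
  machine precision (tested at rtol 1e-9; the residual is FFT round-off).
- **Riemann sum to coarse bins.** Fine-bin masses are summed in groups of
  `adc_ratio` per recorded bin, matching how the ADC coarsens the TCSPC data.

The log likelihood is Σᵢ yᵢ log Pᵢ (multinomial; the total-count factor is a
constant and dropped). MLE fitting uses Nelder-Mead on log/logit-transformed
parameters with standard errors from a finite-difference Hessian. The
integer IRF shift `bshift` is profiled over its support only on request;
synthetic IRFs carry no shift.

Posteriors assume a uniform prior. With ≤ 3 free parameters the posterior is
evaluated on a grid — f_FRET on 201 points in [0,1], noise on 21 points in
[0.8,1], lifetimes on 201 points spanning MLE ± 6 SE (the model is linear in
f_FRET given the lifetimes, so amplitude axes are vectorized over a single
pair of convolved basis curves). With more free parameters a seeded
Metropolis-within-Gibbs sampler is used (5,000 draws after 1,000 burn-in,
split-chain R̂ > 1.1 flagged). Group estimates multiply normalized
per-kinetochore posteriors over a shared grid and marginalize to f_FRET; the
SD of the product posterior is the group SEM, and it shrinks as 1/√n for
concordant inputs. Inputs that place essentially no mass near the combined
mean trigger a conflict warning.

Model selection uses ΔBIC = BIC(single) − BIC(double) with the total photon
count as the sample size; positive values favor the two-exponential model,
and an exact tie reports the single-exponential by parsimony.

FRET→binding conversion divides f_FRET by the calibration slope (default
0.42) and clips to [0,1] with a warning.

## Synthetic data (`ktflim.simulate`)

Every generator is a pure function of its parameters and a seed.

- **IRF**: Gaussian, integrated exactly over fine bins; default FWHM 0.3 ns
  centered at 1.0 ns. The vanishing-width limit reproduces a one-bin delta.
- **Decays**: per-bin independent Poisson draws with mean
  `photons_per_decay · Pᵢ`. The default 300 photons per kinetochore-timepoint
  represents the few-hundred-photon regime of single-kinetochore FLIM.
- **Movies**: 2-D Gaussian spots (σ 1.3 px, 107 nm pixels, Poisson shot noise
  + Gaussian read noise) on sister-kinetochore pairs. Per-condition K-K
  distance distributions are Normal with (mean, SD) of (1.19, 0.19) µm
  untreated, (0.90, 0.10) taxol, (0.87, 0.10) STLC, (1.36, 0.21) 9A-Hec1 and
  (1.16, 0.18) µm under haspin inhibition. The kinematic model is invented
  (only the distributions are constrained by measurement): pair centers
  oscillate sinusoidally along the pair axis (amplitude 0.5 µm, period
  120 s — the ~2 min period of human metaphase oscillations) and the K-K
  distance breathes anti-phase about its mean (amplitude 0.15 µm, period
  50 s), so sister axial velocities about the pair center are exactly
  anti-correlated while raw sister velocities correlate positively through
  the shared center motion. Pair centers keep a 2 µm minimum separation:
  overlapping projected pairs would merge detections, which is a
  2-D-projection artifact rather than a property of a metaphase plate.
- **Model tables, FCS curves, time courses**: direct evaluations of the
  closed forms below plus Gaussian noise.

What these synthetics do **not** emulate: photobleaching, donor
photophysics beyond a mono-exponential, spindle/chromatin background,
3-D defocus, detector afterpulsing, and dead-time. Passing tests establish
the correctness and calibration of the inference machinery under the stated
noise models, not robustness to those real-world effects.

## Geometric FRET calibration (`ktflim.geometry`)

The atomistic conformational ensemble behind the published calibration is
replaced by a desk-scale cylindrical-lattice model: a 13-protofilament
B-lattice cylinder of radius 12.5 nm with 4 nm monomer rise (8 nm dimers,
3-start helical stagger), one TC acceptor anchor per β-tubulin. The donor
sits `donor_offset` = 2.5 nm radially above a binding interface
(intra-/inter-dimer drawn 50/50); its 12 nearest anchors are the acceptor
sites. Conformational flexibility enters as Gaussian tether spread (SD
1.5 nm) applied to every acceptor *and*, coherently per conformation, to the
donor — both fluorophores hang on flexible tethers — with positions falling
inside the microtubule body reflected off the cylinder wall (the excluded
volume of the lattice). Labeling is Bernoulli(f_label) per site; the mixed
lifetime is τ_D/(1 + Σ labeled (R₀/rᵢ)⁶).

Calibration decays draw a bound fraction f_b of molecules with mixed
lifetimes and the rest at τ_D (10,000 expected photons each), fit them with
the two-exponential model (τ_D fixed), and regress fitted f_FRET on true f_b
through the origin over f_b ∈ {0, 0.2, …, 1.0} × 30 repetitions, with a
percentile-bootstrap CI. Under the default geometry, f_label = 0.261 and
R₀ = 5.90 nm the slope computes to ≈ 0.34 (seed-to-seed range 0.334–0.343),
at the lower edge of the 0.42 ± 0.08 calibration band: the discrete lattice
shells concentrate acceptor distances more than a full conformational
ensemble would, slightly under-producing partial-FRET amplitude. The
detectability analysis (ΔBIC vs stand-off distance) reproduces the expected
sign structure: strong positive ΔBIC for surface-bound donors, negative
beyond ~8 nm.

Förster-radius fitting maximizes the multinomial likelihood of a two-
population decay (donor + distance-distribution mixture) over the FRET
population fraction and R₀, with a profile-likelihood 95% CI. A conservative
identifiability guard requires the FRET population to beat the donor-only
model at the 99% level (χ²₂) before R₀ is reported; this also catches the
degenerate direction where R₀ → 0 makes the FRET component mimic the donor.

## Tracking (`ktflim.tracking`)

Detection: local maxima above threshold, refined by median-subtracted
intensity-weighted centroids in a 7×7 window; 0-based pixel coordinates with
pixel centers at integers, scaled by `pixel_size_um` (default 0.107).
Linking: gated greedy nearest-neighbor assignment in order of increasing
displacement, one frame of gap bridging with linear interpolation. Greedy
linking is adequate for sparse kinetochores but fails when per-frame motion
approaches the inter-spot distance — a documented limitation. Drift: the
upsampled cross-correlation of consecutive frames (sub-pixel), with a
normalized-correlation confidence gate (default 0.2) below which zero offset
is assumed with a warning. Pairing: candidate pairs must share ≥ 5 frames,
keep mean separation within 0.5–2.5 µm and displacement-vector correlation
≥ 0.5; conflicts are resolved by maximum-weight matching on the candidate
graph (correlation as edge weight), which, unlike greedy selection, cannot
let two coincidentally in-phase tracks from different pairs consume each
other's true partners. Velocities use the five-point central stencil, exact
for polynomials of degree ≤ 4, with two-frame margins reported as missing.
Classification: leading/trailing from the sign of the pair-center velocity
projected on the pair axis; centered (< 1 µm), off-centered (> 2.5 µm) or
mid relative to the metaphase plate; poleward = sister nearer the pole.
Grouping uses equal-count quantile bins with per-group mean, SEM and IQR.

## Tension model (`ktflim.tension`)

Closed forms as in the README. Fits are inverse-variance-weighted (unit
weights when no SEM is given) trust-region least squares; the A\* ≥ K
constraint is enforced by fitting ΔA = A\* − K ≥ 0. Because the piecewise
break at A\* invalidates the linearized covariance for A\*, its 95% CI is a
profile of the residual sum of squares (F criterion); a replicate study at
the fitted parameter values shows ~96% empirical coverage. Data lying
entirely on one branch of the piecewise relation raise an unidentifiability
error. The per-pool activation constants (K_hd, K_hi) are not separately
identifiable and only the combined (K, A\*) form is fit. The ODE oracle
integrates the full activation/phosphorylation/binding kinetics (LSODA,
windowed until the state change falls below tolerance) and matches the
closed forms to < 1e-6 over a parameter lattice, including the
below-threshold branch where a pool deactivates completely.

The kinase-sensor map is the exact two-anchor linear interpolation between
the pre-inhibition state (sensor 0.540 → f_phos = 1/9) and full inhibition
(0.368 → 0); a printed one-line simplification of that map is arithmetically
inconsistent with its own anchors, so the exact form is used. INCENP
intensity is normalized as (I − I_bg)/(I_mid − I_bg) so that the
inner-centromere peak maps to the 10 µM peak Aurora B concentration.
Exponential drug-response time courses (rising/decaying with an onset
indicator) are fit by weighted nonlinear least squares.

## FCS and labeling fraction (`ktflim.fcs`)

The reference (known concentration and diffusion) model uses the two-photon
factor 8Dτ; the axial waist is eliminated through
w_z = (2/π^{3/2}) · V_eff / w_xy², a convention isolated in one function so
an alternative is a one-line change. The brightness model fixes the PSF
shape and fits the molecule number N and free diffusion time, consistent
with τ_diff = w_xy²/(8D). The background correction factor is
χ² = (S/(S+B))² with S the background-subtracted count rate; it is
configurable because the underlying convention is instrument-specific. Cell
segmentation for the polymer-rate estimate is Otsu threshold + largest
connected component + morphological closing — the downstream arithmetic only
needs the in-mask mean and histogram mode (Freedman-Diaconis bins), so a
contour-accurate segmentation is unnecessary. The labeling chain is
`rate → conc = rate/(ε·V_eff) → total = conc·100/polymer% → fraction =
total/total_tubulin`, reproducing 9.6×10⁴ s⁻¹ → 1.88 µM → 5.22 µM → 26.1%
from the printed inputs.

## Pipeline (`ktflim.pipeline`)

JSON-configured stages (simulate → track → fit_flim → group → model_fit),
all intermediates written to disk, one global seed feeding deterministic
sub-streams. The FLIM stage follows the measurement procedure: τ_D fixed
from the pooled no-acceptor control (histograms pooled by summing counts),
τ_FRET from the aggregate of all kinetochore decays with τ_D fixed, then
per-kinetochore posteriors with both lifetimes fixed, grouped by measured
K-K distance and combined by posterior multiplication. The default run uses
6 pairs × 30 frames × 2 sisters = 360 decays of 300 photons — sized so the
full run, including tracking, completes in seconds while leaving the
injected tension trend statistically unambiguous.

## Problem sizes used in the validation suite

Recovery tests use 10⁴–10⁶ photons per decay as appropriate to the quantity
(10⁶ for lifetime point estimates, 10⁴–10⁵ for amplitude recovery, 5,000 for
the credible-interval coverage study over 200 replicates); the calibration
slope uses 4,000-conformation ensembles, 10,000-photon decays and 30
repetitions; model-fit recovery uses 11–20 data points at noise SD
0.005–0.01, matching the precision of the grouped cell measurements these
synthetics emulate.

## Known limitations

- The geometric calibration is a coarse stand-in; its slope sits at the
  lower edge of the published band (see above) and its distance statistics
  cannot be validated against the atomistic ensemble directly.
- Greedy frame-to-frame linking has no global trajectory model; crossing
  kinetochores at high speeds or long frame intervals will swap.
- Tracking and grouping are 2-D (maximum-projection semantics); z-structure
  is not modeled.
- The uniform-noise floor spreads dark counts evenly over the window; real
  detectors add afterpulsing structure the model does not capture.
- MCMC marginals are reported as independent per-parameter histograms of the
  joint draws; strongly correlated posteriors should be summarized from the
  raw samples, which remain attached to the returned object.
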