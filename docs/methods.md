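# Methods

`gaitstab` analyzes mediolateral (ML) stability control in treadmill walking.
Its core claim structure is a chain of three regressions, computed per trial
over the pooled left and right steps (left-side quantities mirrored so that
*lateral* is positive for both feet), followed by group-level Bayesian tests.

## The three models

**Model 1 — foot placement.** For each normalized swing sample
*i* = 1…51 (toe-off = 1, heel strike = 51):

    FP = β_pos · CoM_pos(i) + β_vel · CoM_vel(i) + error_fp(i)

FP is the demeaned ML position of the newly placed foot at mid-stance,
relative to the stance foot. CoM_pos/CoM_vel are the swing-phase ML center
of mass position and velocity relative to the stance foot, time-normalized
to 51 samples per step and demeaned per sample index. All variables are
demeaned, so no regression here (or below) carries an intercept and R² is
computed about zero. The residual `error_fp` is the *foot-placement error*:
positive means the step landed too lateral.

**Model 2 — ankle strategy.** The residual at mid-swing (*i* = 25) or
terminal swing (*i* = 51) predicts the subsequent CoP shift:

    CoP_shift = β_error · error_fp(i) + error_as

`CoP_shift` is the average ML shift of the CoP in the stance foot's local
anatomical frame during single stance (contralateral toe-off to
contralateral heel strike), relative to the CoP position at single-stance
onset, demeaned across steps. A negative β_error is the ankle-strategy
signature: steps that land too medial are followed by a lateral CoP shift
and vice versa.

**Model 3 — muscle model.** The same CoP shift on three demeaned
early-stance EMG scalars:

    CoP_shift = β_pl·EMG_pl + β_ta·EMG_ta + β_so·EMG_so + error_m

Each scalar is the median of the stride-normalized (1000-sample) envelope
over early stance (first 30% of the stride, heel strike to mid-stance)
multiplied by that episode's duration in seconds. Expected signs: peroneus
longus negative (eversion moves the CoP medially), tibialis anterior and
soleus positive (inversion assistance moves it laterally).

**Absolute explained variance (AEV).** For any of these fits,
AEV = √(mean over steps of fitted²), reported in cm — the magnitude of the
average explained CoP shift. Algebraically AEV = √R² × population SD of the
dependent variable; this identity is enforced to 1e-10 in the tests.

## Group-level inference

Per-participant coefficients and AEVs are tested with JZS default Bayes
factors: a Cauchy(0, √2/2) prior on the standardized effect, marginal
likelihood by adaptive quadrature of the noncentral-t likelihood over the
prior (after an arctangent substitution), one-tailed variants by prior
truncation. The quadrature agrees with pingouin's closed-form JZS routine to
~1e-14 and with a 10⁶-draw Monte-Carlo prior integration within 1%.

Condition × Speed effects on AEV use a Bayesian 2×2 repeated-measures model
comparison: the five candidate mean structures (participant blocks plus
none / Condition / Speed / both / interaction) are fit by least squares and
compared via the BIC approximation BF ≈ exp(−ΔBIC/2). This is deliberately
*not* a replication of JASP's integrated g-prior ANOVA; it is used only for
the direction of model selection (which terms the data prefer), never for
matching printed Bayes-factor magnitudes. The hypothesis suite (H1–H4) runs
one-tailed paired post hocs per speed whenever the preferred model contains
Condition.

## Measurement pipeline

* **Events.** Heel strikes and toe-offs come from per-belt vertical force
  threshold crossings at 5% body weight (event = first sample at/after the
  crossing; at 1000 samples/s sub-sample interpolation is pointless). When
  only a combined CoP is available, a fallback detects the rapid ML
  transfers of the butterfly trace: candidate runs exceed 3× the median
  |ML CoP velocity| and must contain a sample above 10× the median
  (hysteresis against within-stance CoP ramps); transfer onsets are heel
  strikes of the destination side, offsets are toe-offs of the source side.
* **Windows.** Step = toe-off → heel strike; mid-swing = 50% of the step;
  mid-stance (for FP) = 50% of the stance phase (the protocol does not
  define it; this is our choice); single stance = contralateral toe-off →
  contralateral heel strike; early stance = first 30% of the stride,
  matching the EMG window. The final 200 consecutive strides are analyzed
  by default; trials with fewer carry a truncation flag.
* **CoM.** Body CoM = mass-fraction weighted sum of segment CoMs located at
  a configurable fraction along each segment's proximal→distal axis; the
  shipped anthropometric table uses standard adult values and is plainly
  replaceable. ML velocity by central differences (one-sided at the edges)
  at 50 samples/s.
* **Foot frames.** Ankle joint center = malleolar midpoint; temporary
  forward = calcaneus→toe; ML axis = (calcaneus→ankle) × forward; vertical
  = forward × ML; forward re-derived as ML × vertical. The ML axis is
  re-signed (via the medial→lateral malleolar direction) so +ML is lateral
  for either foot; the forward axis flips with it so the frame stays
  right-handed — only the ML coordinate is consumed downstream. Frame origin
  defaults to the ankle joint center; the origin only shifts constants that
  demeaning removes.
* **EMG.** 20 Hz 2nd-order zero-phase high-pass, full-wave rectification,
  50 Hz 2nd-order zero-phase low-pass (effective 4th order each — the filter
  family/order is unstated in gait-EMG lineages, this matches common
  practice). No amplitude normalization: scalars are demeaned only and the
  regression absorbs scale.
* **Units.** Meters and seconds internally; FP/CoP quantities convert to cm
  at the reporting layer. Force (1000/s), kinematics (50/s) and EMG (2000/s)
  stay on native clocks; windows are defined in seconds, so no global
  resampling occurs.

## The synthetic gait generator

The generator emulates the *statistical* structure above, not gait
dynamics. Per step it draws latent variables: an AR(1) CoM offset p (SD
1.5 cm, lag-1 correlation 0.3), an independent decaying-mode amplitude q
(SD 0.8 cm), a foot-placement error e ~ N(0, 0.7 cm), fractional EMG burst
amplitudes ζ (SD 0.5), and residual CoP noise η (SD 0.6 cm). It then
constructs:

* a CoM trajectory whose swing-phase deviation from the stance foot is
  p + q·g(t) on top of a shared sinusoidal mean profile, where g is a
  discrete geometric mode with ratio z solving z − 1/z = −2·Δt·β_pos/β_vel
  at the 50-sample/s kinematic step Δt;
* foot placements FP = mean step width + β_pos·p + e;
* per-belt forces with 5%-BW-exceeding loading from the first stance
  sample, and local-frame CoP ramps during single stance whose
  mean-minus-onset equals the injected shift
  s = β_error·e + Σ gains·(EMG scalar deviations) + η exactly on the
  1000-sample/s grid;
* raw EMG as amplitude-modulated broadband noise whose envelope plateaus at
  the drawn burst level during early stance.

The decaying-mode construction is what makes the generator *exactly*
self-consistent: the pipeline measures CoM velocity by central differences
and resamples both predictors by linear interpolation, and the geometric
mode satisfies β_pos·g + β_vel·(central-difference of g) = 0 identically on
the sample grid, so the foot-placement identity holds at every normalized
index after resampling and demeaning. Noise-free trials therefore recover
every generating coefficient to machine precision end to end, and noisy
trials are exactly unbiased rather than approximately so. Two consequences
are worth knowing:

* stride time is snapped to a 40 ms grid so left- and right-step resampling
  grids share phase (otherwise the shared mean profile would not cancel
  exactly under per-index demeaning), and β_vel must be non-zero;
* the predictors at every swing index span the same two-dimensional latent
  space, so the foot-placement errors at mid-swing and terminal swing
  coincide in synthetic trials. Real data distinguishes i = 25 from i = 51;
  the synthetic cohort cannot, and both indices are carried through the
  pipeline regardless.

Condition emulation: `ankle_constrained` scales β_error, the muscle gains
and the CoP noise by 0.2 (a free default — the study gives no quantitative
effect size for its ankle-moment constraint); `fp_constrained` scales the
FP error and CoM-offset SDs by 0.2. Speeds follow the protocol rule
(1.25·√leg length and 0.63·√leg length m/s) with a proportionally longer
slow-speed stride time. Cohorts perturb coefficients by ~10% between
participants, each participant on an independently spawned random stream.

Default magnitudes were chosen once so that the default cohort looks like a
plausible participant: demeaned FP SD ≈ 1 cm, model-2 trial R² ≈ 0.1 (the
magnitude flagged as a high-end participant), and model-3 AEV of the same
order as model-2 AEV (the two are plotted on comparable cm scales in the
study's figures); the expected coefficient signs (β_error < 0; PL < 0,
TA > 0, SO > 0) are fixed by the physiology.

### What the generator does not emulate

No forward dynamics, no anteroposterior balance control, no double-support
CoP modulation strategies, no marker noise/dropout, no EMG crosstalk or
motion artifact, no drift correction (the midline random-walks a few cm
over 200 strides, which relative measures ignore). Passing tests therefore
establish that the *pipeline measures what it claims to measure* under the
assumed coupling structure — not that real gait obeys that structure.

## Numerical choices and degenerate inputs

* OLS via `numpy.linalg.lstsq`; rank deficiency raises a collinearity error
  (e.g., all-zero EMG scalars), as do designs with no more rows than
  columns or a zero-variance outcome.
* Subset fits (`medial_only` keeps error_fp < 0, `lateral_only` > 0) are
  re-demeaned within the subset and require ≥ 10 steps.
* The JZS quadrature works in log space with a peak-anchored shift, so
  Bayes factors remain finite and accurate out to |t| ≈ 20+ (log BF is also
  reported).
* The low-pass of a rectified signal can undershoot zero; envelopes are
  clipped at zero.
* Quiet standing (no force threshold crossings) yields empty events; empty
  events yield an empty step table; trailing toe-offs without heel strikes
  drop out of the step table.

## Problem sizes in the validation suite

The acceptance checks regenerate everything from scratch: parameter
recovery pools 100 cohort seeds × 30 participants × 200-stride trials
(raw-EMG synthesis skipped — models 1–2 only); the Bayesian sign-structure
check runs 20 directed + 20 null cohort seeds of 30 participants with
50-stride full-EMG trials (group t-statistics are far above the BF = 10
threshold at that length, and the package's own calibration test covers the
200-stride default); constraint-direction and calibration checks use one
30-participant cohort each. These sizes are the package's choice of a
desk-scale design with calibrated power; all are parameters of the
`gaitstab.validation` functions.
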