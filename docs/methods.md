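# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `svvkit`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The verticality estimator

The estimator tracks two states: the velocity-storage content **VS** (deg/s,
3-vector) and the internal gravity-direction estimate **G** (unit 3-vector).
Retinal slip `rSL = Vis − Ω` feeds a leaky integrator together with the canal
signal `V`; the inferred head velocity `Ω = G_o·rSL + G_v·V + VS` rotates
**G**, and a somatogravic leak pulls **G** back toward the gravito-inertial
acceleration direction (GIA) with time constant `T_s`. With the head fixed
and upright, `V = 0` and `GIA = (0, 0, 1)` throughout; visual roll rotation
acts about the naso-occipital x axis, and the reported **bias** is the signed
angle of **G**'s projection onto the y–z plane, positive in the direction of
scene rotation.

Defaults (`ModelParams`): `ko = 0.11 /s`, `kv = 0.2 /s`, `go = 0.16`,
`gv = 0.43`, `kf = 0`, `t_vs = 15 s`, `t_s = 0.74`. Visual noise attenuates
the two visual gains by `(1 − noise fraction)`; the vestibular pathway is
untouched. Two points deserve flagging:

- **Units of `t_s`.** The source literature prints 0.74 without a unit; it is
  taken at face value in seconds. This is small compared with somatogravic
  constants reported elsewhere, but it is the value that, combined with the
  other printed gains, yields a ~7.6° asymptote at 16 °/s — consistent with
  the behavioral plateau of ~7° — so the face-value reading is coherent.
- **Attenuation scope.** Only the visual gains are attenuated with noise.
  (An alternative reading attenuates the vestibular gains too; with `V = 0`
  in this protocol the distinction is inert for the dynamics, but the
  visual-only convention is what `apply_noise_attenuation` implements.)

### The direct-pathway algebra

`Ω` depends on `rSL`, which depends on `Ω`. Rather than lagging one sample,
the loop is solved exactly each step: `Ω = (G_o·Vis + G_v·V + VS)/(1 + G_o)`.
This removes a spurious one-step delay and makes the discrete steady state
match the continuous algebra, which in the small-angle regime gives

    θ∞ = T_s · Ω_vis · (G_o + k_o·T_vs) / (1 + G_o + k_o·T_vs).

The exact steady state replaces `θ` by `sin θ` on the left; at the largest
bias reached in this design (~7.6°) the difference is ~0.3%.

### Integration

Classical fixed-step RK4 at `dt = 1/30 s` (the behavioral recording grid),
with inputs held constant over each step. Gains act on deg/s signals; `Ω` is
converted to rad/s inside `dG/dt` because **G** is a direction vector. **G**
is renormalized to unit length after every step; the per-step drift before
renormalization (from the radial component of the somatogravic leak,
`(1 − cos θ)/T_s·dt ≈ 4·10⁻⁴` at the largest bias) is tracked and asserted
small. Batched integration (`simulate_batch`) evolves all 33 design
conditions as one vectorized state, which is what makes multi-start fitting
affordable; it is bit-compatible with the single-condition path.

Step-halving at `dt = 1/60` changes the bias trace by `< 0.01°`, so the
integration error is far below every tolerance used downstream.

## Stimulus statistics

**Velocity-preserving dot noise.** Each dot's nominal tangential jump
(arc `r·Ω·dt`) is rotated in the image plane by an angle uniform on
±(180·p)° and scaled by `c(p) = πp/sin(πp)`, the reciprocal of the mean jump
cosine, so the expected field velocity is exactly nominal while individual
jumps grow by the factor `c` (≈ 4.28 at p = 0.8). Choices where the source
description is silent:

- noise percent maps linearly to the rotation half-range (100% ↔ ±180°);
- the rotation applies to the planar jump vector, not the annulus arc;
- magnitude (not frame-rate) scaling realizes the `c` correction;
- dots whose scaled jump exits the annulus respawn uniformly inside it
  (limited-lifetime style), preserving density without radial pile-up;
- frame rate defaults to 60 Hz (projector-typical) and is configurable.

A finite frame step makes the realized azimuthal jump the chord, not the
arc, of the rotation — a deterministic relative shortfall of `(Ω·dt)²/3`
(≈ 7·10⁻⁶ at 16 °/s, 60 Hz), negligible against Monte-Carlo error but
accounted for in the zero-noise tolerance of the tests.

**Bar-position noise.** White Gaussian noise is zero-phase filtered
(4th-order Butterworth low-pass at 0.2 Hz, forward–backward), recentred,
rescaled to SD 9.6° and clipped at ±35.9°. The white sequence is padded by
several filter time constants on both sides and only the stationary interior
kept: without the padding, filter start-up transients make the traces peaky
enough that the clip truncates heavily and the pooled SD falls well short of
its calibration. With it, clipping is a rare tail event and the pooled SD
across traces is 9.6° to well within 2%. Spectral confinement is checked
with a Hann-windowed periodogram (a plain rectangular periodogram leaks
>1% of power above 0.25 Hz purely through sidelobes).

## The synthetic cohort

The generator emulates the study conditions: 10 subjects, 6 velocities ×
6 noise levels minus the three infeasible high-velocity/high-noise cells
(33 cells), 2 directions × 4 repetitions spread over 4 sessions
(66 trials/session, 264 per subject), 50-s trials at 30 Hz with motion
during 10–40 s. Each trial is the direction-signed sum of:

1. a random initial bar offset (uniform ±45°) decaying with a 2-s
   exponential as the subject corrects it (the 5–10 s rebasing window makes
   this choice largely immaterial downstream);
2. a saturating-exponential bias `a·(1 − e^(−t'/τ))` during motion, decaying
   with the same `τ` after motion offset (the post-motion course is not
   parameterized by the source; symmetric decay is the simplest choice);
3. residual, imperfectly corrected bar noise — a 1-s first-order low-pass of
   the injected bar noise rescaled to a tracking-error SD of 2°, a value in
   the range of the published single-condition standard deviations — plus a
   constant subject intercept (removed exactly by rebasing).

**Plateau calibration.** The published condition means are 27–40 s *window
means*, not asymptotes, and at the empirical rise constant τ = 11.4 s the
window mean of a unit exponential is only ≈ 0.866 of its amplitude. The
generator therefore sets `a = plateau / f(τ)` with `f` evaluated on the
closed 27–40 s sample window, so the reduced window mean of a noiseless
trial equals the preset value to machine precision. The single τ = 11.4 s
(measured only in the fastest zero-noise condition) is applied to all cells;
per-condition rise dynamics of real subjects will differ.

**Between-subject spread.** Responsiveness multipliers are shuffled Gaussian
quantile midpoints (mean exactly 1, SD 0.4): a stratified design that
produces realistic heterogeneity — including weakly responsive subjects —
while keeping the cohort-mean response calibrated, so the 10-subject grand
mean estimates the preset plateau rather than the preset times a random
cohort factor. An i.i.d. draw would put ≈ 1.1° of SD on the grand mean of
the fastest condition and make cohort-level recovery meaningless at n = 10.

**What passing tests do not show.** The generator's trials are exponential
by construction, so recovering τ = 11.4 s or the preset plateaus validates
the reduction arithmetic, not the shape of human responses; direction
symmetry is likewise built in. Real data could violate either.

**2AFC generator.** Per subject, P("comparison faster") is a cumulative
Gaussian (SD 1 °/s, 2% lapse) of comparison velocity about
`PSE = 6 + (−1.6 + b_s)·noise` with subject slopes `b_s ~ N(0, 0.5)`;
7 velocities × 4 noise levels × 16 repetitions = 448 trials.

## Reduction and inference

Windows are closed intervals on the 30 Hz grid (5–10 s rebase, 27–40 s
analysis). The direction test compares per-subject mean |window mean| of CW
vs CCW trials per condition with paired t-tests at the Bonferroni threshold
0.05/33 ≈ 0.0015, computed on rebased traces (consistent with the stated
order of operations). Folding inverts CW trials and averages all eight
trials pointwise.

The exponential `Y = a(1 − e^(−bx)) + c` is fit by least squares over trial
time 10–40 s with `x` measured from motion onset, initialized at
`a₀ = last-2-s mean, b₀ = 0.1 /s, c₀ = 0` plus five jittered restarts; the
63%-rise time constant `1/b` is reported only for `b > 0`. The group-level
fit applies to the grand-mean trace, not per subject.

Mixed models use `statsmodels.MixedLM` with maximum likelihood (not REML) so
likelihood-ratio comparisons between fixed-effect structures are coherent;
velocity and noise enter as numeric covariates. The LRT statistic is clipped
at zero (optimizer jitter can leave it infinitesimally negative for
equivalent models), and degrees of freedom are the difference in fixed-effect
counts. The PSE-slope model fits a fixed noise slope with per-subject random
slopes; its t statistic is referred to `n_subjects − 1` degrees of freedom —
a deliberately simple surrogate for Satterthwaite's approximation, which is
out of proportion to its role here. A single-subject table falls back to
ordinary least squares, and a numerically degenerate random-slope fit falls
back to the mean of per-subject OLS slopes with its between-subject standard
error.

PSE extraction interpolates the 0.5 crossing linearly in velocity at each
noise level ("contour" extraction on a 7 × 4 grid reduces to per-noise-level
crossings); cells exactly at 0.5 are averaged, non-monotone profiles take
the first upward crossing (flagged), and a profile with no crossing yields a
flagged missing value, never a fabricated one.

## Model fitting

The SSE objective compares predicted and observed bias over the full 30 Hz
motion-period traces of all 33 conditions simultaneously — full traces are
needed to constrain `t_s`, whose signature is the transient shape, not the
asymptote. The pre-motion static interval is an exact fixed point of the
estimator, so the objective simulates from motion onset only (a tested,
lossless shortcut). Free parameters default to {`ko`, `go`, `t_s`} with
bounds gains ∈ [0, 5] and `t_s` ∈ [0.05, 60] s; `t_vs` is held at 15 s and
`kf` at 0. `kv` and `gv` are frozen because `V(t) = 0` in this protocol
renders them unidentifiable — the fitter detects the flat objective
direction and records a warning instead of reporting a meaningless estimate.
Optimization is bounded L-BFGS-B from 10 starts (the spec'd initial values
plus log-uniform draws within bounds), SSE tolerance 1e-12. Refitting the
model to its own noiseless predictions recovers `ko`, `go`, `t_s` to well
under 1% relative error.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to what the
statistics require: 4·10⁶ Monte-Carlo draws for the jump-scale oracle
(keeping the oracle's own standard error below the 10⁻³ comparison band),
≥10⁴ dot-frames per design cell for velocity preservation, 1,000 bar-noise
traces for the pooled SD, 500 null replicates for the LRT type-I rate
(binomial SE ≈ 0.01), and one 10-subject cohort for plateau recovery. Every
stochastic component takes an explicit `numpy` Generator or seed; pipeline
stages derive their streams from one base seed, and reruns are
byte-identical.

## Known limitations

- The cohort generator produces exponential responses with a shared τ and
  symmetric direction behavior; it does not model age effects, the
  studious-vs-not subject clusters, optokinetic nystagmus, or eye movements.
- `kv`, `gv` cannot be estimated from this protocol (no vestibular input);
  fitting them requires head-motion paradigms.
- The mixed models assume Gaussian residuals and a single random intercept
  (random slope for the PSE model); no pairwise post-hoc decomposition is
  provided.
- Statistical comparisons against the original human dataset are out of
  reach (the raw data are unavailable); the package validates structure,
  calibration and self-consistency instead.
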