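# Methods

This note documents the models implemented by `gazebias`, the generative
process behind its synthetic data, the numerical choices inside the two
mixed-model engines, and the limits of what the package's tests can show
about real recordings.

## The measurement model

The package targets a paired-image free-viewing paradigm: on each trial a
positive-valence and a negative-valence image are shown side by side for
3000 ms (after a 1000 ms central fixation cross), gaze is sampled at
150 Hz, and two rectangular areas of interest (AOIs) cover the two images.
The left/right position of the positive image is randomized per trial.
Two trial-level outcomes summarize each gaze stream:

**Dwell-time bias.** Cumulative dwell per AOI is one sampling interval
(1000/150 ms) per valid sample inside the AOI, minus the annotated
duration of every blink whose onset gaze was assigned to that AOI
(floored at zero). Blink time is signal interruption, not engagement;
gaze position is undefined during a blink, so each blink is attributed to
the AOI of the last valid non-blink sample before its onset. The
normalized bias index is

    NBI = (dwell_pos − dwell_neg) / (dwell_pos + dwell_neg) ∈ [−1, +1],

which is antisymmetric in its arguments and invariant to total viewing
time. Trials with zero dwell in both AOIs are excluded (typically
momentary track loss); no other exclusion and no minimum viewing-time
threshold is applied. An AOI that is never fixated has its time to first
fixation (TTFF) coded missing — never interpolated.

**First-look direction.** The binary outcome is 1 when the positive AOI
has the shorter valid TTFF, 0 when the negative AOI does, missing when
neither AOI was fixated. An exact TTFF tie is coded missing: on a 150 Hz
grid a tie carries no directional information, and with continuous
latencies it is a measure-zero event.

A fixation-count bias (same normalized-difference form applied to
per-AOI fixation counts) is computed for the QC association check but is
deliberately not modeled inferentially — it indexes the same allocation
dimension as the dwell NBI (trial-level Pearson r ≈ 0.9 on synthetic
data), and modeling both would only inflate the family-wise error rate.

## Inferential models

Both models use treatment contrasts with reference cell
(adolescent, aggressive), fixed effects condition + cohort +
condition×cohort, and a subject-level random intercept.

**LMM (NBI).** y = Xβ + Zu + e with u_i ~ N(0, σ_b²), e ~ N(0, σ_e²),
fitted by REML. With one variance component, β and σ_e² are profiled out
analytically and the REML criterion is minimized over the variance ratio
θ = σ_b²/σ_e²: every required quantity (GLS normal equations, log-dets,
residual quadratic form) has a closed block form because
(I + θJ)⁻¹ = I − θ/(1+θn_i)·J per subject. The scalar search runs on
log θ (bounded Brent, tolerance 1e−10) with the θ = 0 boundary checked
explicitly. AIC/BIC use the REML criterion with k = p + 2; the interface
does not support comparing different fixed-effect structures under REML.

Fixed-effect t tests use the Satterthwaite approximation:
df = 2·g²/Var̂(g) with g = c′C(θ̂,σ̂_e²)c, where Var̂(g) comes from the
observed information of (σ_b², σ_e²) (central-difference Hessian of the
REML deviance; the surface extends smoothly to slightly negative σ_b², so
differencing at a boundary optimum is well defined) and the gradient of g
by central differences. Degenerate curvature falls back to the residual
df n − p with a warning; θ̂ ≈ 0 uses n − p directly. The implementation
reproduces the classical closed forms: df → n − p as θ → 0, and exactly
s − 1 for the grand mean of a balanced one-way layout.

**GLMM (first look).** Bernoulli-logit with subject random intercept,
fitted by maximizing the exact marginal likelihood; each subject's
integral over b is approximated by adaptive Gauss–Hermite quadrature
(default 25 nodes) recentered at the subject's conditional mode (found by
a vectorized Newton iteration, tolerance 1e−11) and rescaled by the
curvature there. Estimates at 15 and 25 nodes agree to < 1e−4 on
calibrated-scale data; the quadrature matches dense brute-force
integration to < 1e−6 relative error on small fixtures. Optimization is
L-BFGS-B over (β, σ) with σ ∈ [1e−4, 5]; at the lower bound the model
numerically collapses to plain logistic regression (verified against the
logistic MLE). Wald z tests; the covariance of β is the inverse observed
information at (β̂, σ̂), conditional on σ̂. |β| > 15 on the logit scale
triggers a separation diagnostic and flags the fit as non-converged.
AIC/BIC from the maximized marginal likelihood with k = p + 1.

**R².** Variance-partition (marginal/conditional) R²:
σ_f² = Var(Xβ̂) over the sample; marginal = σ_f²/(σ_f²+σ_b²+σ_res²),
conditional adds σ_b² to the numerator; σ_res² is σ̂_e² for the LMM and
π²/3 for the binomial-logit GLMM.

**EMMs and contrasts.** Cell means are c′β̂ at the fixed-effect level
(random intercept at its zero mean), with normal-based CIs on the logit
scale back-transformed by endpoint mapping — this preserves interval
asymmetry on the probability scale and reproduces printed cell
probabilities exactly, which is why it is the default; a
population-averaged variant (probability integrated over b by
Gauss–Hermite) is available and labeled distinctly. Within-cohort
aggressive vs non-aggressive contrasts are differences of cell logits,
exponentiated to odds ratios. The default multiplicity adjustment is
`none` — for a two-contrast family the reference-cohort contrast is then
identical to the Wald test of the condition coefficient — with
Bonferroni, Holm and a studentized-range (Tukey, asymptotic) option by
flag.

## The synthetic-data generator

The generator exists because the downstream pipeline needs data with an
exactly known truth. Defaults encode the motivating study design: 119
participants (children 30+30 aggressive/non-aggressive, adolescents
29+30) × 16 trials.

Latent model per trial of subject i in cell g:

* dwell bias b = clamp(μ_g + u_i + ε, −1, 1), u_i ~ N(0, σ_u²),
  ε ~ N(0, σ_trial²); total in-AOI time T ~ N(2064, 350) ms truncated to
  the available window; dwell splits as T(1±b)/2;
* first look ~ Bernoulli(logit⁻¹(η_g + v_i)), v_i ~ N(0, σ_v²), at a
  latency ~ N(0.79, 0.30) s truncated positive;
* blinks ~ Poisson(0.5)/trial, durations uniform in [100, 400] ms,
  embedded inside in-AOI fixation runs and annotated with id + duration
  the way video-oculography exports do;
* whole-trial track loss with cohort probability 3.75% (children) /
  0.1% (adolescents).

Cell means μ_g and η_g follow the reported treatment-coded effect
structure (μ: −0.17, +0.16, +0.05, −0.03; η: −0.37, +0.29, +0.22, −0.41
relative to aggressive adolescents). The dispersion parameters are not
reported anywhere and were fixed once on two grounds: σ_trial = 0.36 and
σ_u = 0.11 keep clamping of b at ±1 rare (< 1.5% of trials, shifting cell
means by < 0.002, far below the recovery tolerances) while matching the
between/within variance ratio implied by the reported marginal vs
conditional R² of the dwell model (≈ 0.09); σ_v = 0.10 is near zero
because the orienting model's conditional R² equals its marginal R²,
implying a negligible random-intercept variance. Taking the reported R²
values literally would require a trial-level SD near 1.0 — impossible for
a bounded index without heavy clamping — so the generator reproduces the
variance *ratio*, not the absolute residual variance; consequence: the
simulated fixed-effect SEs run ~25% below the printed ones.

All durations snap to the 150 Hz sample grid, and fixation runs are
extended by the embedded blink durations, so blink-corrected dwell and
both TTFFs are recoverable from the sample stream to machine precision —
the generator's per-trial truth table is an exact oracle for the
preprocessing stage. Dwell and first look are driven by separate latent
processes (u_i vs v_i, uncorrelated by default) because the two outcomes
are treated as orthogonal attentional dimensions. Each AOI visit is split
into ~300 ms fixation segments so fixation counts scale with dwell, as in
real scanning. Saccades between AOIs are 20 ms of signal loss, not
smooth trajectories: only fixation-level quantities feed the analysis.
First-look latency is drawn independently of the chosen side because no
side- or group-specific latency is reported.

One physical constraint is worth stating: with a mean first-look latency
of 0.79 s, a saccade gap, and blink time inside the 3000 ms window, the
truncated-normal total-dwell draw is capped by the remaining window, so
realized mean active dwell is ≈ 1.85 s rather than the nominal 2.064 s
(the reported means 0.79 + 2.064 + blink time fill the window almost
exactly, leaving no slack for an independent draw). NBI, first-look
direction and every recovery target are unaffected — both depend only on
the split, not the total.

**What passing tests do not show.** The generator realizes the study's
*design*, not its recordings: real gaze has drift, off-AOI exploration of
screen furniture, partial track loss within trials, fixation-parser
idiosyncrasies, and possibly correlated u_i, v_i. Recovery results
validate the estimators under a correctly specified model; they are not
evidence about effect sizes in any real population.

## Replicate harness and problem sizes

`recovery_experiment` simulates n independent studies (replicate seeds
derived from a master seed by a counter-based SeedSequence scheme), runs
the full pipeline on each, and summarizes per coefficient: mean estimate,
bias, empirical SE, mean model SE, 95% Wald coverage and convergence
rate. The standard configuration is 200 replicates of the full 119 × 16
design (~2 s per replicate end to end); at that size the Monte-Carlo SE
of the mean is ≈ 0.0026 (LMM condition effect) and ≈ 0.013 (GLMM
interaction), comfortably inside the acceptance tolerances of ±0.02 and
±0.06. Non-convergent replicates are recorded and excluded from the
averages.

## Degenerate inputs and tie-breaks

* NBI and count bias raise on an all-zero denominator (such trials must
  have been filtered); vectorized derivation yields NaN instead so the
  validity flag stays authoritative.
* An empty metrics table filters to an empty table with retention
  reported as missing.
* AOI containment uses half-open intervals [x0,x1)×[y0,y1), so a shared
  edge can never be double-assigned; overlapping rectangles are a
  configuration error.
* A fixation straddling AOI entry contributes its first in-AOI sample
  time as TTFF (the most conservative onset).
* A blink spanning an AOI exit is subtracted in full from the onset AOI,
  floored at zero — whether clipping would be more faithful is
  unknowable from the export format, so the simpler rule is used and
  documented.
* Rank-deficient designs (an empty cohort×condition cell) and duplicate
  participant/trial keys raise immediately.

## Known limitations

* One random intercept only — no random slopes or crossed
  (e.g. stimulus-pair) effects, matching the target design but nothing
  richer.
* REML-based AIC/BIC are comparable only across identical fixed-effect
  structures; the API does not guard against misuse beyond documentation.
* The Satterthwaite information matrix is obtained numerically; for very
  small σ_b² the residual-df fallback is used rather than an unstable
  second derivative.
* Normality screening (e.g. Shapiro–Wilk) is out of scope; use scipy
  directly if needed.
* The generator does not simulate pupil size or autonomic signals, and
  stimulus content (saliency/luminance matching of image pairs) is
  entirely outside the package.
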