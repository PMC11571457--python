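# Methods

## Power–duration model and CP estimation

The package parameterises exercise tolerance with the two-parameter
critical-power model in its linear inverse-time form, P = W′·(1/t) + CP.
CP (W) marks the boundary between the heavy and severe intensity domains
(the maximal metabolic steady state); W′ (J) is the fixed budget of
supra-CP work. The estimator is ordinary least squares of trial mean power
on 1/t, which is exact for any set of ≥2 distinct durations generated by
the model. The canonical trial set is 12, 7 and 3 min. Diagnostics exposed:
R², the standard error of the CP intercept, and the point count. A negative
fitted W′ (non-maximal trials) is returned with a warning rather than
rejected, so batch analyses can screen on the flag. Hyperbolic, work–time
and 3-min all-out variants are deliberately out of scope: every downstream
computation consumes (CP, W′) and is agnostic to how they were estimated.

## W′ balance

Time is a uniform 1 Hz grid; a sample at t covers [t, t+1), so integrals
are rectangle sums, exact for ergometer-held constant-power steps. A trace
stores `wbal[k]`, the balance after k samples, hence `wbal[0] = W′`.

**Integral (discounted-sum) model.** Each joule spent above CP recovers
exponentially with time constant τ_W′:

    W′bal(t) = W′ − Σ_{u<t} (P(u) − CP)₊ · e^(−(t−1−u)/τ)

(the freshest sample carries no discount). Computed with the O(n)
recursion S_i = S_{i−1}·e^(−1/τ) + w_i and verified in the tests against an
independent O(n²) double-loop of the definition (agreement to 1e-9 relative
on the W′ scale). τ follows the standard exponential law
τ = 546·e^(−0.01·D_CP) + 316 s with D_CP = CP − mean(sub-CP power over the
series); deeper recovery reconstitutes faster, bottoming out at 316 s. A
series with no sub-CP samples has no recovery information; the continuous
limit τ → ∞ is used, under which the model reduces exactly to undiscounted
suprathreshold work. `tau_override` pins τ for sensitivity analyses.

One behavioural subtlety: because all past depletion decays at every step,
the integral balance can *rise* during supra-CP work when a large prior
deficit's decay outweighs a small fresh depletion. This is a property of
the discounted-sum formulation, not a bug; the monotone
"deplete-above/recover-below" picture holds exactly only for the
differential model.

**Differential model.** Depletion is linear in P − CP; recovery is a
first-order approach, W′bal(t+1) = W′ − (W′ − W′bal(t))·e^(−(CP−P)/W′),
whose constant-power closed form is matched by the per-sample iteration to
machine precision. Reconstitution approaches W′ asymptotically and never
overshoots.

Balances are not clamped: a session can overspend the model's W′ (the
report then shows a negative %balance) and an `exhausted` flag marks
balance ≤ 0. Fatigue classes on remaining %W′: ≥80 moderate, 40–<80 heavy,
0–<40 severe, <0 exhausted-beyond-model. The 80% boundary reflects the
observation that a 4-min terminal recovery restores roughly 80–100% of W′;
the inner boundaries are package conventions.

## Session design

The SML-INT skeleton is a 15-min warm-up at 75 W, then
30 s/1/3/7-min work bouts with 30 s/1/3/4-min recoveries at 60 W
(mid-range of "below 75 W"; configurable). Work powers are solved by
bisection on [CP + 0.1, CP + 3W′/duration] against an exact constant-power
bout propagation of the chosen model; the end-of-bout balance is strictly
decreasing in power, so bracketing doubles as a solvability check.
Tolerance is 1 J on the end balance (three orders of magnitude below the
0.1 kJ reporting precision), max 60 iterations.

Two target modes:

* **end-balance targets** (default 40/10/5/0 %W′): a progressive run-down
  with the final bout ending fully depleted;
* **depletion pattern** (67/55/50/33 %W′ per bout): fixes each bout's
  suprathreshold spend, with the closed-form solution
  P = CP + depletion/duration. The cumulative spend is 205% of W′.

For the integral model the designer fixes τ up front from the plan's
sub-CP samples (warm-up + recoveries), which are all known before any work
power is solved; since solved work powers always sit above CP, a fresh
evaluation of the finished series derives the identical τ, making design
and re-simulation consistent to the solver tolerance. Repetitions per block
default to 1 and are configurable; the designer is fully deterministic.

## Per-interval report

Per interval: arithmetic means of V̇O₂, HR and power; V̇O₂peak as the
highest 30-s rolling mean within the interval (intervals shorter than 30 s
use their full length, so short bouts still report a peak); METs as mean
V̇O₂/3.5 ml·kg⁻¹·min⁻¹; lactate attached from the sample nearest a work
interval's end (≤10 s), matching end-of-bout fingertip draws. Relative
intensities are 100·value/anchor against the athlete's V̇O₂ at CP and GET
and the HR_max/HR_CP/HR_GET anchors. Reporting rounds half-up: integer
percent, one decimal for V̇O₂/METs/lactate. For the CP-test reference
column the METs row derives from peak rather than mean V̇O₂ by convention
of that column's construction in the pipeline.

## Ramp test analysis

V̇O₂max attainment uses three criteria — plateau (<1.5 ml·kg⁻¹·min⁻¹
increase across the final two workloads), RER > 1.15, and HR above 95% of
the age-predicted maximum (220 − age, strict inequality) — with ≥2 required
for a V̇O₂max classification, otherwise V̇O₂peak. "Workloads" are
consecutive 60-s bins of the 25 W·min⁻¹ ramp (25 W each), each summarised
by its 30-s trailing mean; the binning is a package convention. GET is
detected by the v-slope method: an exhaustive two-segment linear fit of
V̇CO₂ against V̇O₂ (≥10 points per segment), taking the breakpoint with
minimal total squared error and requiring a genuine slope increase
(tolerance 1e-6 relative, so collinear data return "no threshold" instead
of float noise).

## Synthetic data generator

The generator emulates a cohort of master road cyclists: body mass
70.1 ± 8.7 kg, age 31.7 ± 9.0 y, CP 3.9 ± 0.3 W·kg⁻¹, W′ 14.8 ± 4.8 kJ,
V̇O₂max 57.5 ± 4.5 ml·kg⁻¹·min⁻¹, independent normals truncated at 3 SD.
Threshold anchors are fixed ratios of the individual maxima —
V̇O₂@CP = 0.81·V̇O₂max, V̇O₂@GET = 0.65·V̇O₂max, HR_CP = 0.92·HRmax,
HR_GET = 0.77·HRmax, HRmax = 220 − age — chosen so cohort statistics
resemble a trained masters sample. One athlete per 14 is female (warm-up
and ramp start loads 50/75 W instead of 75/100 W).

Responses: V̇O₂ demand is linear in power, pinned so demand at CP equals
the athlete's V̇O₂@CP; measured V̇O₂ relaxes toward demand
mono-exponentially (τ = 30 s, exact per-sample decrement, so noise-free
responses equal the continuous solution), plus a slow component of
0.3 ml·kg⁻¹·min⁻¹ per kJ of current W′ depletion while above CP, capped at
V̇O₂max. HR relaxes (τ = 45 s) toward a linear map of V̇O₂ onto
[60 bpm, HRmax]. V̇CO₂ is piecewise-linear in V̇O₂ with its breakpoint at
the athlete's GET (slope 0.85 below, above pinned so RER reaches 1.2 at
V̇O₂max) — giving ramps both a detectable v-slope breakpoint and RER > 1.15
at exhaustion. Ramp tests terminate after V̇O₂ stays within 1.5
ml·kg⁻¹·min⁻¹ of V̇O₂max for 30 s, landing near the 8–12-min design window
for typical athletes. Time trials draw mean power from the power–duration
model plus optional Gaussian noise (default 0 W, so fits are exact closed
loops; 5 W for realism studies). Lactate follows
d[La]/dt = 60·(P−CP)₊/W′ − 0.02·([La]−1) by explicit 1 Hz Euler, sampled at
work-bout ends. Measurement noise is i.i.d. Gaussian (1 ml·kg⁻¹·min⁻¹ V̇O₂,
2 bpm HR) added before the physiological caps. All draws derive from
explicit seed sequences split per signal, so every generator is
bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about measured data: breath-by-breath noise is neither
autocorrelated nor intensity-dependent; cadence, drift, temperature and
day-to-day variability are absent; the HR map is a single linear function
of V̇O₂, so simulated steady-state HR at CP sits below the athlete's
HR_CP anchor (relative-HR report rows for synthetic sessions are
correspondingly conservative); the lactate constants produce realistic
shapes but stylised (high) magnitudes for near-full-depletion bouts; and
time trials are generated directly from the fitted model's own equation, so
closed-loop CP recovery validates the estimator's algebra, not the model's
physiological adequacy.

## Statistics

Per variable, a one-way ANOVA across the interval conditions plus the
CP-test control. The F decomposition is computed with per-group centring
(the textbook shortcut loses all precision when groups are near-constant,
as the designed depletion percentages are); zero within-group variance
yields F = 0 or ∞ by the sign of the between-group spread. Dunnett
many-to-one adjusted p-values are estimated from 50,000 seeded Monte-Carlo
draws of the exact null max-|t| distribution (multivariate normal with the
many-to-one correlation √(n_i n_j/((n_i+n0)(n_j+n0))) scaled by a shared
χ²/df), with add-one smoothing; shared draws make the adjustment monotone
in |t|, and k = 2 reduces to the two-sample pooled t-test within Monte-Carlo
error. Brown–Forsythe (ANOVA on |x − group median|) is reported alongside
as a variance-homogeneity check — it is not itself a multiple-comparison
correction, and the package reports it in that companion role. Stars follow
the 0.05/0.01/0.001 convention, two-sided.

Because the conditions are repeated measurements on the same athletes, the
between-group ANOVA ignores the within-subject correlation; the pipeline
replicates that design as specified and this caveat applies to its
p-values.

## Problem sizes and seeds

Default analyses use cohorts of 14 athletes. Verification suites use sizes
chosen to make the checks sharp while staying quick: 100 random 20-min
traces for the brute-force W′bal comparison, 200 replicates for the noisy
CP-bias check, 100 athletes for GET recovery, 1000 replicates for the
type-I calibration (Dunnett draws reduced to 200 there, since the
calibration event is the ANOVA main effect). All seeds are explicit.

## Known limitations

* τ_W′ constants (546/316/0.01) are population-level; no individual τ
  fitting from repeated-exhaustion trials.
* Single-τ recovery; no bi-exponential reconstitution.
* The %W′ reconstitution of a recovery interval is expressed relative to
  W′ (consistent with the depletion rows), not relative to the preceding
  deficit.
* CP and GET stored as V̇O₂ anchors and CP as watts are independent fields;
  the package never converts between them.
* No device-file parsing (FIT/TCX/GPX) and no plotting.
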