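# wprime-kinetics

Modelling toolkit for critical-power-based training analysis in cycling:
fit the power–duration relationship, track W′ balance through interval
sessions, design sessions that deplete W′ to target levels, summarise the
physiological responses per interval, and compare conditions statistically.
It is aimed at exercise physiologists and sport scientists who prescribe
interval training relative to critical power rather than V̇O₂max.

## The models

**Critical power.** Mean power over a maximal effort of duration *t* follows

    P = W′ · (1/t) + CP

where CP (W) is the asymptote of the power–duration relationship — the
highest power with a metabolic steady state — and W′ (J) is the finite work
capacity above CP. Ordinary least squares of mean power on 1/t over a set of
time trials (here 12, 7 and 3 min) gives W′ as the slope and CP as the
intercept.

**W′ balance.** Above CP, W′ is spent at P − CP joules per second; below
CP it reconstitutes. Two formulations are implemented:

* *integral* (discounted sum): every joule spent above CP recovers
  exponentially, `W′bal(t) = W′ − Σ_{u<t} (P(u)−CP)₊ · e^(−(t−1−u)/τ)`,
  with `τ = 546·e^(−0.01·D_CP) + 316` s, where D_CP is CP minus the mean
  sub-CP (recovery) power. Evaluated at 1 Hz with an O(n) recursion.
* *differential*: linear depletion above CP and a first-order return to W′
  below it, `W′bal(t+1) = W′ − (W′ − W′bal(t))·e^(−(CP−P)/W′)`.

**Session design.** The SML-INT structure (30 s / 1 / 3 / 7-min work with
30 s / 1 / 3 / 4-min recoveries below 75 W after a 15-min warm-up) is solved
so each work bout's power depletes W′ balance to a prescribed level, by
bisection on power against an exact bout simulation.

**Statistics.** Per report variable, a one-way ANOVA across conditions with
Dunnett many-to-one comparisons against the CP-test control (adjusted p by
seeded Monte-Carlo of the max-|t| null) and a Brown–Forsythe
variance-homogeneity check.

A synthetic-data module generates cohorts of master cyclists
(CP ≈ 3.9 ± 0.3 W·kg⁻¹, W′ ≈ 14.8 ± 4.8 kJ, V̇O₂peak ≈ 57.5 ± 4.5
ml·kg⁻¹·min⁻¹) with mono-exponential V̇O₂/HR on-kinetics, a slow component
above CP, ramp tests, time trials and lactate responses, so the whole
analysis runs end to end without measured data. See `docs/methods.md`.

## Worked example

```bash
python analysis/03_design_sessions.py --seed 42
```

prints, for a simulated athlete (CP 304.3 W, W′ 5.4 kJ):

```
paper-pattern session:
  S-work-30s       30 s @  425.6 W (1.40x CP)
  S-work-1min      60 s @  354.1 W (1.16x CP)
  M-work-3min     180 s @  319.4 W (1.05x CP)
  L-work-7min     420 s @  308.5 W (1.01x CP)
  per-bout depletion (%W'): 67, 55, 50, 33
  final balance: 80.3 %W'
```

Each line is one solved work interval: the constant power that makes the
bout spend exactly the configured fraction of W′ (67/55/50/33%) under the
integral balance model. Shorter bouts need much higher power relative to CP;
the cumulative spend is 205% of W′ — possible only because recovery
intervals reconstitute W′ in between — and the final 4-min recovery returns
the athlete to ≈80% of W′ (moderate fatigue).

The other drivers follow the study flow: `01_simulate_cohort.py` (cohort
characteristics), `02_fit_critical_power.py` (ramp test, gas-exchange
threshold by v-slope, V̇O₂max criteria, CP/W′ fits),
`04_session_report.py` (full pipeline and the per-interval cohort report),
`05_group_statistics.py` (ANOVA + Dunnett vs the CP-test condition).

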