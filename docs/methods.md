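# Methods

## Model

The estimator treats the left ventricle and the arterial tree as two
coupled elastances on a pressure–volume diagram.  End-systolic elastance
`Ees = Pes/(EDV − SV − V0)` is the slope of the end-systolic
pressure–volume relationship (an index of contractility); effective
arterial elastance `Ea = Pes/SV` lumps the arterial load into a single
slope.  Dividing one by the other eliminates Pes:

    Ees/Ea = SV/(EDV − SV − V0)   ⇒   EDV = SV·(1 + Ea/Ees) + V0.

So EDV follows from stroke volume once the coupling ratio is known, and
the whole problem reduces to estimating Ees/Ea noninvasively.

That estimate rests on a bilinear approximation of the time-varying
ventricular elastance E(t): one line for isovolumic contraction (duration
PEP), one for ejection (duration ET), with slope ratio k.  Under that
approximation the hypothetical peak isovolumic pressure — what the
ventricle would generate if the aorta were clamped — is
`Pmax = Pad·[1 + (ET/PEP)·k]`, where Pad is the pressure at which ejection
begins, taken here as the cuff diastolic pressure.  Since the pressure
rises Pes→Pmax (ventricle) and Pad→Pes (artery) are produced by the same
ejected volume, `Ees/Ea = (Pmax − Pes)/Pes`.  Eliminating Pmax gives the
one-line coupling equation

    Ees/Ea = (Pad/Pes)·(1 + k·ET/PEP) − 1,

and the empirical calibration `k = 0.53·(Ees/Ea)^0.51` closes the system.
End-systolic pressure itself comes from the cuff regression
`Pes = 0.205·SBP + 0.898·DBP + 0.4214`.

Assumptions worth keeping in mind: V0 = 0 (reasonable for normal systolic
function, wrong in dilated failing hearts — `estimate_edv` exposes `v0`
for sensitivity analysis); the bilinear E(t) approximation; the k
calibration, an experimental regression imported as-is; and cuff pressures
standing in for central pressures.

## The nonlinear solve

Substituting the k relation, the root problem is
`f(x) = c1·x^0.51 − x + c0 = 0` with
`c1 = (Pad/Pes)·0.53·(ET/PEP)` and `c0 = Pad/Pes − 1 ≤ 0`.
f is strictly concave on x > 0, rises from f(0+) = c0 to a maximum at
`x_peak = (0.51·c1)^(1/0.49)`, then falls to −∞.  Consequences the solver
is built around:

- **Two roots, one physiological.**  When c0 < 0 and f(x_peak) > 0 the
  equation has a tiny spurious root left of the peak and the physiological
  root on the decreasing branch.  The solver targets the decreasing-branch
  root.  Newton starts at `max(x0, 2·x_peak)` with x0 = 1 (the coupling
  value at which k was calibrated): for a concave function every tangent
  from the region right of the peak crosses zero at or beyond the root, so
  the iteration is provably convergent there.  Iterates are clamped to
  stay strictly positive (`x ← max(x_new, x/10)`), since the fractional
  powers are undefined at x ≤ 0.
- **No root can exist.**  If f(x_peak) < 0 (low Pad/Pes together with a
  short ET/PEP) the measurements are mutually inconsistent under the
  model.  The solver raises a no-solution error reporting f at the bracket
  ends; the cohort pipeline marks such subjects excluded rather than
  aborting, because measurement noise can genuinely produce such records.
- **Tolerances.**  Convergence is declared at |f(x)| ≤ 1e-9 (dimensionless
  residual; the equation is scale-free), followed by one polishing Newton
  step, which brings the root itself to near machine precision.  Fallback:
  bisection on (x_peak, 100] when Newton stalls or leaves (0, 100].
  Defaults: max 50 iterations; the exponent pair (0.53, 0.51) is
  configurable in `SolverConfig` for sensitivity work.

## Synthetic cohorts

The generator's purpose is validation: it draws ground-truth states and
runs the model equations in reverse, so every emitted noise-free
observation satisfies all of them simultaneously and the estimator must
recover the true EDV exactly (this is tested to < 1e-6 relative, and holds
to ~1e-15).  Defaults emulate a healthy young-adult cohort:

| quantity | law | default | unit |
|---|---|---|---|
| Ees/Ea | uniform | 0.8 – 2.5 | – |
| EDV | normal, truncated | 95 ± 15, in (60, 139) | ml |
| Pad (= DBP) | normal | 73 ± 9, ≥ 45 | mmHg |
| PEP | normal | 96 ± 13, ≥ 50 | ms |
| pulse pressure | normal | 44 ± 10, ≥ 15 | mmHg |
| noise SD (pressures / timings / SV) | Gaussian, additive | 3 mmHg / 5 ms / 4 ml | – |

SBP = Pad + pulse pressure, and the true Pes follows from the cuff
regression; sampling the pulse pressure rather than Pes keeps SBP and DBP
correlated the way real cuff readings are and gives SBP a realistic ±13
mmHg spread.  The elastance scale is then Ea = Pes/SV, Ees = ratio·Ea.
ET and SBP are derived, not sampled, which guarantees internal consistency
of the noise-free round trip.  Infeasible draws are resampled (capped,
logged).  Measurement noise is additive, Gaussian, independent across
observables.

What the generator does **not** emulate: inter-subject covariance beyond
the SBP–DBP link above, beat-to-beat variability, non-Gaussian device
error, V0 > 0 states, and pathological hemodynamics.  Passing recovery
tests therefore demonstrates correctness of the estimation chain, not
clinical accuracy on real patients.

## Agreement statistics

Differences are oriented reference − test, so an overestimating test
method yields a negative bias.  SD uses the n−1 denominator.  The
limits-of-agreement multiplier defaults to 2 — the convention under which
the published bias/SD pair (−11.2 ± 12.7 ml) reproduces the published
limits (−36.6, +14.2 ml) exactly — with 1.96 available as an argument.
Percentage error is `100·m·SD / mean(reference)` (the reference mean
alone, not the grand mean), flagged acceptable at ≤ 30 %, boundary
inclusive.  Regression of test on reference is ordinary least squares;
R² is the squared Pearson correlation.

## Pipeline conventions

- Exclusion filtering marks records, never drops them: missing required
  fields, or the configured volume at/≥ 140 ml.  The cutoff field is
  configurable (`edv_ref` by default, `sv` available) because the
  normal-range motivation for the cutoff concerns EDV while stroke-volume
  phrasing also circulates; the boundary is inclusive.
- Timings are stored in milliseconds; only ET/PEP enters the equations,
  so the unit cancels.  A `--timings-seconds` flag converts on read.
- Input validation is on by default and loud (clinical inputs warrant
  failure over silent coercion); a `validate=False` escape hatch exists on
  the pure functions for contract-level testing.

## Problem sizes

The validation suite uses 48-subject noise-free cohorts (exact-recovery
check), a 500-subject cohort across a 0.5×–4× noise ladder (percentage
error: 11 → 79 %, monotone), and 1000 random pressure/timing tuples for
the Newton-vs-bisection cross-check.  All of it runs in seconds; sizes
were chosen to make Monte-Carlo assertions stable, and the cohort size 48
mirrors the validation-study scale the defaults emulate.

## Known limitations

- V0 = 0 biases EDV downward in hearts with elevated unstressed volume.
- The k calibration and the Pes regression are population-level empirical
  relations; subject-level deviations propagate directly into EDV.
- The no-root region of the coupling equation means noisy records can be
  unestimable; they are reported as excluded, which slightly biases
  cohort statistics at high noise.
- Cuff pressures are peripheral; central-to-peripheral pulse
  amplification is not modelled.
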