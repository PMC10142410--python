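# edvcalc

Noninvasive estimation of left-ventricular **end-diastolic volume (EDV)** —
the standard volumetric surrogate for cardiac preload — from measurements
that require no imaging and no arterial line: cuff systolic/diastolic blood
pressure, the systolic time intervals (pre-ejection period PEP and ejection
time ET), and stroke volume (SV).

It is written for anesthesiologists, intensivists and hemodynamics
researchers who want a preload index that could, in principle, be tracked
continuously from an ECG, a phonocardiogram and pressure cuffs, and for
anyone studying ventricular-arterial coupling from systolic time intervals.

## The method

The route to EDV goes through ventricular-arterial coupling, the ratio of
end-systolic elastance to effective arterial elastance, Ees/Ea:

1. **End-systolic pressure** from cuff pressures (empirical regression):

   `Pes = 0.205·SBP + 0.898·DBP + 0.4214`  (mmHg)

2. **Coupling** from pressures and timings.  Approximating the
   time-varying ventricular elastance bilinearly over isovolumic
   contraction and ejection, the hypothetical peak isovolumic pressure is
   `Pmax = Pad·[1 + (ET/PEP)·k]` with Pad the diastolic (ejection-onset)
   pressure and k the slope ratio of the two segments, and
   `Ees/Ea = (Pmax − Pes)/Pes`.  Combining the two with the empirical
   relation `k = 0.53·(Ees/Ea)^0.51` gives one nonlinear equation in
   x = Ees/Ea,

   `x = (Pad/Pes)·(1 + 0.53·x^0.51·ET/PEP) − 1`,

   solved by Newton's method (analytic derivative, bracketed-bisection
   fallback on the physiological branch).

3. **Volume** from the elastance definitions `Ees = Pes/(EDV − SV − V0)`
   and `Ea = Pes/SV`:

   `EDV = SV·(1 + Ea/Ees) + V0`,  with `V0 = 0` assumed for hearts with
   normal systolic function.

The package also provides a forward hemodynamic simulator (the same
equations run in reverse, so synthetic cohorts with known ground truth can
validate the inverse estimator), Bland–Altman method-agreement statistics
with percentage error and the ≤ 30 % clinical-acceptability rule, and a CSV
pipeline with a command-line interface.

## Worked example

Estimate from cohort-mean measurements (SBP 117, DBP 73 mmHg, PEP 96,
ET 286 ms, SV 61 ml):

```python
from edvcalc import BeatObservation, estimate_subject

obs = BeatObservation("means", sbp=117, dbp=73, pep=96, et=286, sv=61)
r = estimate_subject(obs)
c, e = r.coupling, r.estimate
print(f"Pes     = {c.pes:.4f} mmHg")
print(f"Ees/Ea  = {c.ees_over_ea:.4f}   (k = {c.k:.4f}, Pmax = {c.pmax:.2f} mmHg, "
      f"{c.iterations} Newton iterations)")
print(f"EDV     = {e.edv_calc:.2f} ml   (ESV = {e.esv_calc:.2f} ml)")
```

prints

```
Pes     = 89.9604 mmHg
Ees/Ea  = 1.2432   (k = 0.5922, Pmax = 201.80 mmHg, 5 Newton iterations)
EDV     = 110.07 ml   (ESV = 49.07 ml)
```

i.e. this subject's contractility slightly exceeds its arterial load
(Ees/Ea ≈ 1.24, the healthy working point), and the filled ventricle held
about 110 ml, of which 61 ml were ejected.

The same workflow from the shell — simulate a 48-subject synthetic cohort,
estimate every subject, then check agreement of the estimates against the
simulated ground-truth EDV:

```sh
edvcalc simulate --n 48 --seed 7 -o cohort.csv --truth truth.csv
edvcalc estimate cohort.csv -o results.csv
edvcalc validate results.csv -o report.txt
```

```
n pairs             : 48
bias (ref - test)   : 0.46 ml
SD of differences   : 9.41 ml
limits of agreement : -18.36 to 19.29 ml (bias ± 2·SD)
percentage error    : 20.1 %
acceptable (PE<=30%): yes
R^2                 : 0.518
slope               : 0.882
intercept           : 10.58 ml
```

At the default measurement-noise settings the estimator is essentially
unbiased against the simulated truth, and its percentage error stays below
the 30 % clinical-acceptability cutoff.

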