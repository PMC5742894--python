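# melcurve

Modelling of the diurnal melatonin secretion rhythm from sparse blood
profiles: bell-curve fitting, DLMO phase markers, gamma shape scoring and
nonparametric cohort comparison.

Plasma melatonin in healthy children follows a bell-shaped 24-h rhythm —
low during the day, rising in the evening, peaking in the small hours.
In circadian sleep disorders (Angelman syndrome is the motivating case,
alongside pediatric epilepsy cohorts) the rhythm can be delayed,
stretched, or lose its bell shape entirely, degenerating into a roughly
triangular course.  `melcurve` quantifies all of this from a handful of
timed blood samples (typically every 3 h over 24 h) per subject.

## The model

The concentration curve is the 24-h-periodic, Gaussian-like bell

```
MLT(t) = b1 + b2 · exp( −ln 2 · [ (cos(π(t−b3)/12) − 1) / (cos(π·b4/24) − 1) ]² )
```

with

| parameter | meaning | units |
|---|---|---|
| `b1` | minimum (daytime baseline) concentration | pg/mL |
| `b2` | nocturnal release amplitude | pg/mL |
| `b3` | phase shift — clock time of the secretion maximum | h |
| `b4` | estimated sleep duration = FWHM of the peak | h |

The form is fixed by three constraints: maximum `b_max = b1 + b2` at
`t = b3`, full width at half maximum exactly `b4`, and 24-h periodicity.

Derived circadian phase markers (dim light melatonin onset/offset) are
read off at relative thresholds of the amplitude, which normalises away
inter-subject amplitude differences:

```
DLMOon50  = b3 − b4/2          DLMOoff50 = b3 + b4/2
DLMOon25  ≈ b3 − (2/π)·b4      DLMOoff25 ≈ b3 + (2/π)·b4
```

(all clock times reduced mod 24; the exact 25% crossings are also
available via `dlmo25_exact`).

Departure from the physiological bell shape is measured per sample point
by the **gamma statistic**: the minimum modified Euclidean distance of
the measurement from the fitted curve in joint time–concentration space,
standardised by tolerances of 20 min and 5% of the measured value.  A
profile whose largest gamma stays ≤ 2 is bell-like; `max γ > 2` flags
disturbed (e.g. triangular) secretion.

Cohorts are compared parameter-by-parameter with the Mann–Whitney U test
(exact enumeration for small tie-free samples), plus Kruskal–Wallis for
more than two groups.

## Worked example

```python
from melcurve import ModelParams, b_max, dlmo, fit_profile, max_gamma
from melcurve.simulate import group_default_spec, generate_cohort

p = ModelParams(b1=5.0, b2=150.0, b3=3.5, b4=8.0)
print(b_max(p))                 # 155.0  (pg/mL, peak concentration)
d = dlmo(p)
print(d.on50, d.off50)          # 23.5000  7.5000  (clock hours: onset the
                                # previous evening, offset at 07:30)

spec = group_default_spec("AG", 3, seed=42, noise_cv=0.05)
cohort = generate_cohort(spec)
for prof, (sid, row) in zip(cohort.profiles, cohort.ground_truth.iterrows()):
    fit = fit_profile(prof)
    score = max_gamma(prof, fit.params)
    print(sid, row.waveform, round(score.max_gamma, 2), score.verdict)
```

prints

```
AG_1 tent 6.23 disturbed
AG_2 tent 32.87 disturbed
AG_3 bell 1.1 bell
```

— the two triangular profiles are flagged by the gamma score (6.23 and
32.87, both far above the threshold 2), while the bell-shaped subject
stays below it, even though all three *fits* explain > 94% of the
variance: gamma detects shape mismatch that global fit quality misses.

The same workflow is available from the shell:

```bash
melcurve simulate --group AG --n 9 --seed 1 --out cohort.csv
melcurve run --input cohort.csv --out results/
```

which writes per-subject fitted parameters and markers
(`fitted_params.csv`, `fits.json`), per-point gamma scores
(`gamma_scores.csv`), group comparisons (`comparison_*.csv`), boxplot
summaries and a run manifest.

`MelatoninCurveModel` is a scikit-learn regressor (time → concentration),
so it composes with sklearn tooling; `fit_profile` is the convenience
wrapper used throughout.

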