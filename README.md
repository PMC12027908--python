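# diastolica

Invasive left-ventricular pressure-curve analysis and biomarker-based
long-term survival modelling for cohorts evaluated for diastolic dysfunction.

Patients undergoing left heart catheterization for suspected diastolic
dysfunction can be risk-stratified from three families of measurements:
serum biomarkers (natriuretic peptides BNP / NT-proBNP / MR-proANP, sST2,
galectin-3, MR-proADM), echocardiography (E/E′, ventricular and atrial
volumes, strain), and the invasive pressure curve itself.  `diastolica`
implements both halves of that workflow as a tested, reusable library:

* **Pressure-curve analysis.**  From a sampled LV pressure trace it segments
  cardiac cycles at dP/dt upstroke onsets, detects end-diastole, peak systole
  and the post-relaxation end-systole, selects a five-beat end-expiration run
  (the respiratory trough of the beat-to-beat baseline), and reports — as the
  unweighted mean over the five beats — LVEDP, end-systolic pressure, maximum
  and minimum dP/dt, the contraction integral ∫(dP/dt)dt from end-diastole to
  peak systole, the relaxation integral |∫(dP/dt)dt| from peak to
  end-systole, and the diastolic pressure–time integral ∫P dt of the filling
  phase.  By the fundamental theorem of calculus the two dP/dt integrals
  equal the pressure differences between their bounds, which is the internal
  consistency check the test suite leans on.  Diastolic dysfunction is
  called as LVEDP > 15 mmHg.

* **Survival workflow.**  Descriptive comparisons by first-year mortality
  with Shapiro–Wilk routing (t-test / Mann–Whitney / Fisher's exact),
  univariate Cox regression, Kaplan–Meier curves for median-dichotomized
  predictors, multivariable Cox models built by forward stepwise selection
  under BIC = −2·log PL + k·ln(d) (d = number of events), percentile
  bootstrap confidence intervals over 1000 patient resamples, and Harrell's
  C-statistic — run in a *non-invasive* scenario (clinical + serum + echo
  covariates) and an *invasive* scenario that adds the catheterization
  parameters.

Because real patient data of this kind are access-restricted, the package
ships two first-class simulators that make every stage testable end to end:
a waveform generator with closed-form fiducials, dP/dt extrema and integrals
(sin²/cos² rise and fall plus linear filling), and a cohort generator with
log-normal biomarkers anchored to published medians/IQRs and a Weibull
proportional-hazards event process acting on median-dichotomized covariates
(≈14.5% observed mortality over a median ≈1.66-year follow-up at defaults).

## Worked example

```python
from diastolica.waveform import WaveformParams, simulate_waveform
from diastolica.hemodynamics import compute_hemodynamic_params

wf, truth = simulate_waveform(WaveformParams(noise_sd=0.0, resp_amplitude=0.0))
hp = compute_hemodynamic_params(wf, k=5)
print(round(hp.lvedp, 2), round(hp.min_dpdt, 1), round(hp.contraction_integral, 2))
```

prints `12.09 -1963.7 157.89`: the extractor recovers the simulated
end-diastolic pressure of 12 mmHg to within 0.1 mmHg, the closed-form
minimum dP/dt of −1984 mmHg/s to ~1% (the 21-sample moving average
attenuates the derivative peak slightly), and the contraction integral to
within 0.11 mmHg of its analytic value 158 mmHg (= 170 − 12).

```python
from diastolica.cohort import CohortConfig, simulate_cohort
from diastolica.pipeline import ScenarioConfig, run_analysis

cohort = simulate_cohort(CohortConfig(seed=7))
report = run_analysis(cohort, ScenarioConfig(scenario="invasive", bootstrap_B=200))
print(report.summary["death_pct"], report.selected_model.c_statistic)
```

prints `15.4 0.794…`: this particular 110-patient draw shows 17 deaths
(15.4%) and the stepwise model reaches a concordance of 0.79.  With only
~16 events, which covariates survive selection varies noticeably between
draws — exactly the small-sample instability one should expect at this
cohort size (see `docs/methods.md`).

The same steps are available from the shell:

```bash
diastolica simulate-waveform --preset highrisk-dd --seed 7 --out wf.csv
diastolica analyze-waveform --in wf.csv --out params.json
diastolica simulate-cohort --n 110 --seed 7 --out cohort.csv
diastolica run --scenario invasive --cohort cohort.csv --out report/
```

The numbered scripts under `analysis/` run the full study narrative —
phenotype waveforms, extraction validation, cohort calibration, both
scenario analyses — and write their tables under `results/`.

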