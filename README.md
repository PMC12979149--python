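# pacehrv

Ultra-short heart-rate-variability assessment of the parasympathetic
response to rapid atrial pacing — a reproducible simulation, measurement and
statistics pipeline for intraoperative electrophysiology.

## The problem

During an electrophysiological study, a 30-s burst of rapid atrial pacing
(100 bpm) provokes a brief vagal surge at the sinus node: beat-to-beat
cycle-length variability jumps immediately after pacing and returns to
baseline within two minutes. Classical HRV needs minutes of ECG; here the
response must be read from just **four consecutive sinus PP intervals**
("ultra-short" HRV), measured before (periods A, C) and immediately after
(periods B, D) each of two pacing bursts two minutes apart. Quantifying this
response in real time matters for procedures that modulate cardiac
parasympathetic innervation (e.g. cardioneuroablation or pulmonary-vein
isolation), where an intraoperative readout of vagal tone is otherwise hard
to obtain.

Two indices are computed per 4-interval window:

```
RMSSD = sqrt( Σ_{i=1..n-1} (PP_{i+1} − PP_i)² / (n−1) ),  n = 4
ΔPP   = PP_max − PP_min
```

together with the sinus node recovery time (SNRT, last stimulus to first
spontaneous sinus beat), cSNRT = SNRT − baseline cycle length, and the AV
Wenckebach point. Cohort analysis uses Friedman's ANOVA, Bonferroni-corrected
Wilcoxon signed-rank tests on the prespecified pacing contrasts (A–B, C–D;
threshold p < 0.025), Bland-Altman bias/SD/%bias (limits of agreement
deliberately omitted at this window length), second-order difference plots,
positive-delta frequencies, and Shapiro-Wilk-gated Spearman/ICC/CCC
repeatability. Because no patient-level data are public, a calibrated
synthetic cohort generator (with ground truth for recovery testing) stands
in for the 50-patient cohort; externally annotated beat tables can enter the
pipeline unchanged at the analyze stage.

## Worked example

```bash
pacehrv run --config configs/default.yaml --seed 1 --out out/
pacehrv report --summary out/summary.json
```

or equivalently in Python:

```python
import pacehrv as ph
bundle = ph.run_study(ph.RunConfig(), "out", seed=1)
```

This simulates 50 patients through the full two-burst protocol, extracts the
A–D windows (enforcing the ectopy/artifact repeat rule), and prints, among
other tables:

```
== Median (IQR) per period ==
-- RMSSD (ms) --
  period A: 17.7 (13.1–26.1)
  period B: 41.9 (25.6–56.1)
  period C: 20.2 (11.8–26.2)
  period D: 51.0 (30.1–69.8)
  Friedman p = <0.001; A-B p = <0.001, C-D p = <0.001, A-C p = 0.794, B-D p = 0.123

== Bland-Altman agreement for RMSSD (ms) ==
Periods   Bias [ms]   SD [ms]   Bias (%)
A vs. B   -26.45      25.96     -79.34
A vs. C   -1.55       13.54     -7.44
C vs. D   -31.87      23.99     -86.40
B vs. D   -7.33       31.95     -14.91
```

Reading: resting 4-beat RMSSD sits around 18 ms and jumps to ~42–51 ms
immediately after each pacing burst (both prespecified contrasts significant
at p < 0.025), while the two baselines A and C are statistically
indistinguishable — the vagal surge is large, reproducible, and fully
recovered within the 2-minute gap. The negative A–B/C–D biases encode the
post-pacing increase (differences are oriented first period minus second);
the small A–C bias shows baseline stability. The run directory also contains
per-patient beat-series files, a ground-truth table, `patient_metrics.csv`,
an audit log of discarded windows, Bland-Altman and SODP figures, and a
machine-readable `summary.json`; reruns with the same config and seed are
byte-identical.

`pacehrv analyze --beats DIR --out OUT` runs the same measurement and
statistics on externally supplied beat tables (CSV: `# key=value` metadata
lines, then `time_ms,label` rows with labels sinus / pace_stim / ectopic /
artifact).

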