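# tremormark

Surface-EMG biomarkers for quantifying and predicting the intraoperative
efficacy of deep brain stimulation (DBS) on parkinsonian resting tremor.

During the intraoperative testing stage of DBS surgery, a few minutes of
surface EMG (sEMG) recorded from a tremulous limb with the stimulator off
and on carry enough information to quantify how well stimulation suppresses
resting tremor — and to predict the clinical improvement a patient will show
on the tremor subscale of the MDS-UPDRS (items 15–18, "UPDRS-t"). This
package implements that analysis as a tested, reusable pipeline for
clinical neurophysiologists and methods researchers:

1. **Conditioning** — 20–200 Hz minimum-order Butterworth band-pass
   (zero-phase), 1-s segmentation with automatic amplitude-clip artifact
   rejection, full-wave rectification, 50-ms sliding RMS envelope.
2. **Twelve features** per recording, in three families:
   amplitude/power (wRMS, MMAV1, MMAV2, WL, Peak(f)PSD, MDP, MNP),
   frequency / motor-unit firing rate (Peak(f), FR, ZC, SSC), and
   regularity (sample entropy). The ~5 Hz tremor rhythm lies below the EMG
   pass band, so Peak(f) and Peak(f)PSD are read off the Welch spectrum of
   the rectified RMS envelope.
3. **Cohort statistics** — improvement rates `IR = (off − on)/off`
   (clinical: `(pre − post)/pre`), paired DBS-off/on t-tests, a Spearman
   co-correlation map of the significantly changed features, and selection
   of the features whose IR tracks the clinical IR (p < 0.05, uncorrected).
4. **Prediction** — leave-one-out cross-validated Gaussian-process
   regression (constant mean, ARD squared-exponential kernel with learned
   noise) of the clinical IR from the selected feature IRs, judged by the
   Pearson correlation between predicted and true IR and a label-permutation
   null: `p_perm = #{r_perm ≥ r_true}/P`.
5. **Synthetic cohorts** — a generator of paired DBS-off/on recordings
   (tremor bursts at 4.93 ± 0.98 Hz riding on band-limited EMG noise at
   512 Hz) with UPDRS-like scores whose latent improvement is coupled to the
   EMG suppression, so the entire pipeline is testable without patient data.

## Worked example

Simulate a 39-patient cohort and run the full analysis:

```bash
tremormark simulate --out demo_cohort --n 39 --seed 42
tremormark analyze --manifest demo_cohort/manifest.csv --out demo_report \
    --permutations 200
```

The run prints:

```
LOOCV Gaussian-process prediction of clinical improvement
==========================================================
patients:            39
features:            WL, MMAV1, MMAV2
LOOCV method:        per_fold
Pearson r:           0.2366
parametric p:        0.147
permutation p:       0.04 (200 permutations)
permutation p (+1):  0.04478
```

and writes `paired_change_table.csv`, whose head (rounded) reads

| feature  | DBS-off mean | DBS-on mean | IR mean | paired-t p |
|----------|-------------:|------------:|--------:|-----------:|
| PeakF    | 4.74 Hz      | 4.74 Hz     | 0.00    | 1.000      |
| PeakFPSD | 19.3 dB      | 3.1 dB      | 0.87    | <0.001     |
| wRMS     | 22.7 µV      | 6.5 µV      | 0.71    | <0.001     |
| SampEn   | 1.45         | 1.80        | −0.36   | <0.001     |
| UPDRS-t  | 14.9         | 3.3         | 0.77    | <0.001     |

Reading this: stimulation suppresses every amplitude/power and firing-rate
feature (11 of the 12 features change at p < 0.05) but leaves the tremor
peak frequency untouched — DBS quiets the bursts without breaking their
pathological rhythm — while sample entropy *rises* as the over-regular
tremor pattern is restored toward noise-like activity. The clinical tremor
subscale improves by 77% on average. `selected_features.csv` lists the
features whose improvement tracks the clinical improvement (here WL
R = 0.43, MMAV1 R = 0.41, MMAV2 R = 0.41, …, p < 0.05 each); the top three
feed the GPR, whose leave-one-out predictions correlate with the true
per-patient improvement (r = 0.24) and beat the 200-fold permutation null
(p = 0.04).

The same analysis is available as a library:

```python
from tremormark import (SimParams, synth_cohort, AnalysisConfig,
                        analyze_patients)

patients = [p.record for p in synth_cohort(SimParams(seed=42))]
report = analyze_patients(patients, AnalysisConfig(n_permutations=200))
print(report.prediction.summary())
```

or, statsmodels-style, for the prediction stage alone:

```python
from tremormark import ImprovementGPR

model = ImprovementGPR.from_ir_table(report.ir_table, ["wRMS", "MNP"])
results = model.fit(seed=0)
results.permutation_test(n_permutations=1000)
print(results.summary())
```

## Layout

```
src/tremormark/
  io.py          recordings, cohort manifests, EDF (optional)
  preprocess.py  filtering, segmentation, rectification, envelope
  features.py    the 12 features, Welch spectra, tremor-peak detection
  stats.py       improvement rates, paired tests, selection
  prediction.py  LOOCV-GPR model + permutation test
  synthetic.py   tremor-EMG cohort generator
  pipeline.py    end-to-end orchestration and reports
  cli.py         `tremormark simulate | features | analyze | predict`
docs/methods.md  model assumptions, parameter choices, limitations
```
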