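# spikewave

Interplay of interictal epileptiform discharges (IEDs) and local wake slow
waves (LoWS) in intracranial EEG, from raw multichannel signal to a
patient-level prognostic classifier.

## The problem

In presurgical epilepsy evaluation, intracranial EEG biomarkers are used to
delineate the tissue whose removal gives seizure freedom.  IED rate alone
localises the seizure-onset zone but predicts surgical outcome poorly.
`spikewave` implements an analysis of the *temporal interplay* between IEDs
and wake slow waves — 0.5–4 Hz half-waves accompanied by a transient
suppression (downstate) of high-gamma (HG, 45–130 Hz) power: how long after
a slow wave the next discharge occurs, and vice versa, corrected for event
incidence.  The prognostic claim being tested: short IED→LoWS delays in
resected tissue of patients with good outcome and in spared tissue of
patients with poor outcome, i.e. a resection x outcome interaction on the
corrected delay

    corrected_delay ~ 1 + resection + Engel + Engel x resection + (1 | patient)

fitted as a REML linear mixed model with Satterthwaite denominator degrees
of freedom, plus a threshold classifier on the per-patient ratio of
resected over nonresected corrected delay.

The package is fully testable without clinical data: a synthetic-data module
generates 1/f background with wake alpha, injects spike-wave discharges and
downstate-gated slow half-waves with ground-truth logs, and simulates
surgical cohorts with a plantable outcome x resection effect.

## What's inside

| module | role |
| --- | --- |
| `spikewave.synth` | synthetic recordings, event injection, cohort simulation |
| `spikewave.io` | EDF + TSV read/write, 60-Hz notch, alpha/delta wake mask |
| `spikewave.ied` | Hilbert-envelope IED detector, burst collapsing |
| `spikewave.lows` | half-wave LoWS detector: duration, percentile, IED exclusion, HG downstate gate |
| `spikewave.interplay` | event rates, pairwise delays, incidence correction, SOZ rule, preictal tables |
| `spikewave.excitability` | peri-IED HG spectrograms, baseline-normalised IED-HG, delay-excitability mixed model |
| `spikewave.morphology` | waveform features and IED/LoWS cluster separability (odds ratios) |
| `spikewave.stats` | Engel linearisation, ROUT outliers, outcome LMMs, Wilcoxon tests, repeated-measures ANOVAs |
| `spikewave.classify` | delay-ratio metric, ROC, repeated train/validate threshold classifier |
| `spikewave.mixed` | REML mixed models with in-package Satterthwaite df |
| `spikewave.studies` | end-to-end seeded simulation studies |

See `docs/methods.md` for the models, parameter defaults and their
rationale.

## Worked example

Simulate a 10-channel, 10-minute recording with known event times, run both
detectors, and measure recovery:

```python
from spikewave import studies

out = studies.detector_recovery(seed=1)
for k, v in out.items():
    print(f"{k}: {v:.3f}" if isinstance(v, float) else f"{k}: {v}")
```

```
ied_recall: 0.912
ied_fp_per_min: 0.020
lows_recall: 0.865
nondownstate_rejection: 0.928
detected_ied_rate_per_min: 0.640
detected_lows_rate_per_min: 3.180
n_ied_injected: 34
n_lows_injected: 163
```

91% of injected discharges are recovered with 0.02 false detections per
wake-minute per channel; 87% of injected slow waves survive the full chain
(geometry → percentile → IED exclusion → downstate gate), while waves
injected *without* a downstate are rejected 93% of the time — the gate is
doing the discriminating.  The detected rates (0.64 IEDs/min, 3.2 LoWS/min)
track the configured clinical incidences.

Fit the outcome model on a simulated cohort with a planted
outcome x resection effect:

```python
from spikewave.synth import SimConfig, CohortSpec, simulate_cohort
from spikewave.interplay import cohort_outcome_table
from spikewave.stats import fit_outcome_lmm

cohort = simulate_cohort(CohortSpec(n_patients=20, seed=7),
                         SimConfig(n_channels=20, duration=600.0))
table = cohort_outcome_table(cohort)
res = fit_outcome_lmm(table, "eq4")
t = res["engel:resection"]
print(f"interaction: F[1, {t.df_den:.2f}] = {t.F:.3f}, p = {t.p:.4f}")
```

```
interaction: F[1, 18.00] = 10.262, p = 0.0049
```

The Engel x resection interaction is detected with a fractional-df omnibus
F, the same reporting style the mixed models produce throughout.

## Command line

A thin CLI covers the shell-usable stages:

```sh
spikewave simulate --out data/ --duration 120 --channels 4 --seed 0
spikewave detect --edf data/sim_ieeg.edf --channels data/channels.tsv --out events.tsv
spikewave rates --events events.tsv --wake-minutes 1.0
```

The statistics and classification stages operate on in-memory tables and
are used as library functions.
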