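# Methods

`spikewave` analyses the dynamic relationship between two interictal
biomarkers in wake intracranial EEG — interictal epileptiform discharges
(IEDs) and local wake slow waves (LoWS) — and asks whether their temporal
interplay carries prognostic information about epilepsy surgery.  This note
documents the models, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Signal model and preprocessing

Recordings are channels x samples matrices in microvolts.  Sampling rates
below 500 Hz are rejected: the high-gamma band (45–130 Hz) that anchors both
the downstate gate and the excitability proxy is unresolvable at, e.g.,
256 Hz.  A 60-Hz notch (second-order IIR, Q = 30, applied forward–backward)
removes line noise with zero phase shift, because every downstream statistic
is built from event *peak times* and phase distortion would bias the delay
estimates.  An IIR notch is not exactly idempotent on broadband input — each
application removes residual transition-band power (~2% relative RMS on 1/f
input) — which we accept in exchange for the phase behaviour.

Only awake data are analysed.  Wakefulness is defined per 10-s window by the
alpha/delta bandpower ratio (8–12 Hz over 0.5–4 Hz, averaged across
channels, threshold 1.0); window length and threshold are configurable since
the underlying clinical criterion is not standardised.  Channels flagged
outside gray matter are dropped at ingest; a stand-in artifact rule drops
channels with > 20% flatline samples or > 1% of samples above 1 mV.

## IED detection

The detector follows the Hilbert-envelope construction: band-pass 20–80 Hz
(4th-order Butterworth, zero-phase), envelope as the modulus of the analytic
signal, candidate events where the envelope exceeds 3.5x its mean over the
channel's wake samples.  Two implementation details are ours:

* the envelope is smoothed with a 15-ms moving average before thresholding.
  A genuine discharge sustains its envelope over a ~60-ms core, while
  band-limited background excursions last about one over the bandwidth
  (~15 ms); smoothing therefore suppresses the false-positive tail by an
  order of magnitude at a ~1% recall cost.
* the secondary amplitude criterion — discard candidates below 4x the mean
  envelope of the 5-Hz high-passed signal — is evaluated on the
  **peak-to-peak** amplitude over a causal window (−40 ms to +130 ms around
  the envelope peak), the conventional way spike amplitude is measured and
  wide enough to include the after-going slow wave that carries much of a
  spike-wave complex's broadband amplitude.

Supra-threshold excursions closer than 40 ms are merged; envelope ties break
to the earlier sample.  Both thresholds are ratios to per-channel means, so
detection is invariant to any global rescaling of the signal.  Bursts —
chains of same-channel events with inter-peak gaps <= 0.2 s — are collapsed
to their first event to avoid counting propagated discharges; chaining is
gap-based (each event within 0.2 s of the previous extends the burst)
rather than window-from-first.

## LoWS detection

Candidates are half-waves between consecutive zero crossings of the
0.5–4 Hz filtered signal, both polarities, with duration in [0.25, 1] s
(one-sample tolerance at the bounds: a continuous-time duration exactly at
0.25 s digitises to 127 or 128 samples at 512 Hz).  Candidates below the
channel's 90th amplitude percentile are discarded (strictly-below keeps only
strictly-above events), as are candidates within 1 s of a detected IED on
the same electrode, and — as a degenerate-input guard — "waves" below 1% of
the channel's raw RMS, which are numerical filter residue on inputs with no
slow-band content.

The **downstate gate** keeps a candidate only when its high-gamma power
(squared Hilbert envelope of the 45–130 Hz signal) averaged inside the
half-wave is at least 30% below the mean over two flanking baselines
(peak ± [0.5, 1.5] s).  The 30% margin is set by the sampling variability of
band-power estimates at this bandwidth and window length (relative SD
~0.15–0.2, heavier-tailed on 1/f background): a smaller margin lets
estimator noise through (measured ~12% false gate passes at a bare
"strictly lower" rule), while a genuine downstate sits at a power ratio of
(1 − depth)^2 ≈ 0.2 at depth 0.8 and is unaffected.  The margin is
configurable, including zero.

For preictal analyses the amplitude percentile threshold is computed once on
interictal data and applied unchanged (`amplitude_thresholds=` argument), so
rate comparisons are not confounded by threshold re-estimation.

## Delays and the incidence correction

Each IED is paired with the next same-channel LoWS (and symmetrically for
the opposite direction); unpaired sources and pairs crossing a wake-segment
boundary are censored.  Raw waiting times mechanically depend on event
incidence, so each delay is divided by its expectation under a
homogeneous-rate model of the target train — equivalently multiplied by the
target rate in events per second.  The corrected delay is dimensionless with
1 = "as expected by chance"; for a Poisson target train it is exactly
Exp(1), giving two testable calibrations: the per-channel median converges
to ln 2 ≈ 0.693, and the distribution is invariant to thinning the target
train.  Channel-level summaries use the median (robust to the heavy right
tail of waiting times); patient-level summaries average channel medians
within resected and nonresected groups.  An alternative shuffle-based
expectation is deliberately not implemented: the analytic Poisson limit
provides a sharper validation target and the homogeneous correction is the
minimal one that removes the rate confound.

## Excitability

For each IED a Hanning-taper spectrogram of the ±3 s peri-event window is
computed with 0.2-s windows at 90% overlap, giving exactly 5-Hz frequency
steps; rows 45–130 Hz are retained.  The excitability sample is
log(mean HG power in ±50 ms) − log(mean HG power in the −3 to −1 s
baseline).  The baseline interval is ours: it is the pre-event epoch that
lies outside both the discharge and its 1-s slow-wave exclusion zone.  The
log-ratio makes the measure invariant to signal rescaling and gives the
identity ied_hg = 0 on stationary input.  The association with the waiting
time since the last slow wave is estimated by a linear mixed model with a
per-patient random intercept and random slope; when that fit is singular the
slope is dropped and flagged.

## Mixed models and their degrees of freedom

All outcome models are REML linear mixed models fitted through statsmodels.
The rate and delay models regress the patient x resection-group summary on
resection status, linearised Engel score and their interaction, with a
per-patient random intercept; the extended model adds SOZ, lesional-status
and therapy variance components.  The headline quantity is always the
Engel x resection interaction: a quantity is prognostic exactly when its
resected/nonresected difference varies with surgical outcome.

Denominator degrees of freedom use the Satterthwaite approximation computed
in-package (statsmodels does not provide it): for each contrast,
df = 2 (l'Cl)^2 / (g'Ag) with g the finite-difference gradient of l'C(θ)l
in the variance parameters and A the inverse negative Hessian of the
profiled REML log-likelihood.  The implementation agrees with lmerTest to
four decimals on shared fixtures (cross-checked in the test suite via
Rscript).  Variance estimates at the boundary are flagged as singular; at
the boundary the interaction F reduces exactly to the ordinary
least-squares F, which the tests assert.

Engel classes map to an ordinal covariate (I→1 … IV→4, subclasses at
quarter steps); any replacement table must be strictly monotone.  Good
outcome is Engel I–II by default.  ILAE scores are supported by substituting
the ordinal column.

Repeated-measures ANOVAs for the seizure analyses (region x period, and the
3-way with event kind) are computed by the standard fully-within
decomposition — each effect tested against its interaction with subject —
because no installed package covers three within factors; the two-factor
margin is cross-checked against pingouin.  Post hoc contrasts of
preictal-minus-interictal differences are Holm-corrected.

Outlier screening re-implements the robust-regression-plus-FDR procedure
(Q = 1%): residuals from a robust location are scaled by the 68.27th
percentile of absolute residuals (small-sample corrected) and flagged by a
false-discovery walk from the most extreme point inward.  For location-only
data this degenerates to a robust-location residual test.

## Outcome classifier

The per-patient metric is the ratio of resected over nonresected mean
corrected IED→LoWS delay; low values (short delays in removed tissue) point
toward good outcome.  Whole-sample discrimination is summarised by a
rank-based AUC with a Hanley–McNeil z test.  The train/validate procedure
uses 70/30 stratified splits: the training set fixes the
accuracy-maximising threshold (ties to the lower threshold), held-out
patients are classified, and all of OR, accuracy, F1, sensitivity,
specificity, NPV and PPV are accumulated over (by default) 1,000 repeats
and summarised as median [IQR], with the threshold's SD reported as a
stability measure.  Chance level is established by re-running the entire
procedure under label permutations; the permutation statistic is the *mean*
over repeats (the median lives on a coarse accuracy grid whose ties make
permutation p-values conservative and non-uniform, while the mean is nearly
continuous and calibrates correctly — verified by KS uniformity on null
cohorts).  Splits sample within class in metric-sorted order, which makes
results exactly invariant to patient ordering.  The split fraction, repeat
count and threshold objective are configurable; none are prescribed by the
clinical source.

## The synthetic-data generator

The generator is the package's test bed, not a biophysical model.  It
emulates exactly the features the pipeline consumes:

* **Background**: Gaussian 1/f^slope noise (default slope 1) with a spectral
  knee at 80 Hz (roll-off slope + 2 above), overall RMS 50 µV, plus an
  8–12 Hz alpha rhythm at 2x the delta-band power toggled in 30-s blocks —
  enough structure for the alpha/delta wake criterion and realistic
  envelope statistics in the detection bands.
* **IED template**: a 60-ms Mexican-hat core (spectral peak ~28 Hz)
  followed by an opposite-polarity slow wave at 2.2x the core amplitude
  (total support 150 ms), normalised to unit peak 20–80 Hz envelope and
  scaled to `ied_amp_factor` times the channel's mean wake envelope
  (default 5).  The after-going wave is what makes the broadband amplitude
  criterion satisfiable at realistic injection strengths, as in clinical
  spike-wave morphology.
* **LoWS template**: a raised half-sine of 0.3–0.9 s, scaled 1.5x above the
  channel's own 90th percentile of background half-wave amplitudes; when a
  downstate is planted, the 45–130 Hz content of the background is
  multiplicatively suppressed by `downstate_depth` (default 0.8) under a
  Tukey window for the wave's duration.
* **Timing**: homogeneous Poisson per channel at the documented clinical
  incidences (IEDs 0.71/min, LoWS 3.82/min of wake), 0.5-s refractory
  spacing, and 1.2 s between IEDs and slow waves so injected waves are not
  consumed by the detector's own post-IED exclusion.
* **Cohorts** (event-level): per patient, Engel classes are apportioned by
  largest remainder; channel positions include a tight cluster so the 10-mm
  seizure-onset rule has members; ~30% of channels are resected, seizure-
  onset channels preferentially.  The LoWS train has piecewise-constant
  intensity — λ/f from each IED until the next slow wave, λ otherwise — so
  by memorylessness every IED-to-next-LoWS waiting time is exactly
  Exp(λ/f): the corrected delay is exactly f·Exp(1) and the planted
  parameter means what it says.  On resected channels
  f = 1 + `planted_interaction` · (Engel − 2.5); a patient-level lognormal
  multiplier (SD 0.1) gives the random intercept real variance to absorb.

The default planted interaction is 0.20 corrected-delay units per Engel
step, fixed by an a-priori power calculation: channel summaries are medians
of Exp-distributed delays (a multiplicative shift f moves the median by
f·ln 2), the resected/nonresected group means average ~6 and ~14 channel
medians with per-median SD ≈ 0.42, giving a slope standard error ≈ 0.044 at
20 patients and hence ~0.9 power at ~18 denominator df for an effect of
0.185–0.20.

What the generator does **not** emulate: ictal waveforms (preictal periods
are labelled segments with shifted rates), sleep architecture beyond the
alpha toggle, electrode geometry beyond coordinates, spatial correlation
between channels, non-Gaussian background transients, or any biophysical
coupling between discharges and slow waves.  Passing tests therefore
demonstrate that the pipeline measures what it claims on signals with known
truth — not that the clinical effect itself is reproduced.

## Study sizes

The packaged studies (shared by the test suite and `scripts/acceptance.py`)
use: detector recovery on 10 channels x 10 min; corrected-delay calibration
on 100 independent 60-min train pairs; interaction calibration on 500 null
and 200 planted cohorts of 20 patients x 20 channels x 10 min;
excitability recovery on 100 simulated sample sets of 10 patients x 30
samples; classifier evaluation on one 55-patient cohort (20-min recordings) with 500 repeats
and 500 permutations plus 40 null cohorts; separability on 6 rendered
patients.  These sizes put Monte-Carlo error comfortably inside the margins
being tested while keeping each study in the minutes range on one core.

## Known limitations

* The downstate gate, the excitability baseline, the incidence-correction
  formula, the Engel subclass interpolation and the classifier's
  split/repeat scheme are reasoned defaults for procedures whose clinical
  source does not print the exact recipe; all are configurable.
* The Satterthwaite machinery assumes the REML Hessian is informative; at
  variance boundaries it falls back toward residual df, which is mildly
  liberal when the true intraclass correlation is positive but small.
* EDF export quantises to 16 bits over the per-channel range; round-trips
  are exact only to that quantisation step.
* Event-level cohort simulation treats the whole recording as wake;
  rendered recordings toggle alpha blocks instead.
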