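# Methods

This note documents the models, numerical choices, and limitations behind
`eegwm`. It describes what the code computes and why; every number quoted
here is either a configurable default or a quantity the test suite itself
computes.

## Study design being emulated

A cohort of 18 participants performs two associative-learning tasks (visual
and audiovisual). Each recording contains a 1-min pre-task baseline, six
contiguous acquisition segments, and a 1-min post-task baseline, on a
64-channel 10-10 montage. The six segments correspond to staircase phases of
the task: a new stimulus–response pair is added once the previous ones are
mastered, so segment index doubles as a working-memory-load index. Segments
1–3 are labeled *low load*, 4–6 *high load*; crossing load with task
modality gives the 4-class decoding target.

The behavioral task itself (trial timing, responses, retrieval and
generalization phases) is out of scope; the staircase is emulated only as
segment timing, with durations drawn uniformly from 21–37 s per participant
and rounded to whole seconds so each recording spans an integer number of
EDF data records.

## Synthetic data generator

Background activity is, per channel, 1/f ("pink") noise of 10 µV sd plus
5 µV white noise, mutually independent across channels — deliberately no
volume-conduction or head model, so any spatial structure in the features
must come from a planted effect. Spatial realism is limited to ROI
membership: effects are planted into the four ROI channel lists (left/right
frontal, left/right parieto-occipital).

Three plantable effect families mirror the three feature families:

* **Modality band-power offsets** (`modality_power_effect`, dB per band per
  modality; default θ: audiovisual +3 dB). A band-limited oscillator
  (10 µV sd) runs through the whole recording; during task segments its
  amplitude is scaled by the per-modality offset. Each labeled span
  additionally receives a slow amplitude perturbation shared across channels
  (`power_effect_jitter_db`, default 1.0 dB sd), modeling vigilance/state
  drift. Without it the planted classes separate perfectly, which is both
  physiologically implausible and statistically degenerate: the permutation
  null of perfectly clustered data is bimodal at {0, 1}. With 1 dB of state
  drift, modality decoding from θ power lands near 0.87 — the regime the
  method is meant to operate in — and the null is well behaved.
* **Load-dependent phase coupling** (`load_coupling_effect`, one von-Mises
  concentration per load segment per band; defaults decay 6 → 0.3 across
  segments for θ and α). Frontal ROI channels share a band-limited reference
  component (20 µV sd); parieto-occipital ROI channels carry the same
  component with a smoothly varying circular phase lag whose concentration
  is the planted κ of that segment (κ = 0 in baselines). Larger κ ⇒ tighter
  phase locking ⇒ higher SI; the decaying default makes fronto-parietal
  coupling strongest under low load.
* **Modality-dependent phase-of-power coupling** (`cfc_effect`, modulation
  depth per band pair per modality; default θ–β: visual 0.15, audiovisual
  0.7). ROI channels receive a low-frequency tone plus a high-frequency
  carrier whose amplitude is `(1 + depth·cos φ_low)`-modulated during task
  segments.

Phase lags are generated by drawing von-Mises samples at 2 Hz and
interpolating along the shortest circular path; the oracle used in tests is
the circular resultant of the *realized* per-sample lag series, so the
interpolation does not bias the comparison. Determinism: the cohort seed
feeds a `SeedSequence` tree (participant → layout/visual/audiovisual), so
identical configurations are bit-identical, and participants are
independent of cohort size.

What the generator does **not** emulate — and what passing recovery tests
therefore cannot show about real data: volume conduction and reference
effects (real scalp channels are heavily correlated), artifacts (blinks,
EMG; the pipeline assumes artifact-free input), non-stationary oscillation
frequency, genuine behavioral coupling between load and signal power, and
1/f slope variation across subjects.

## Signal processing

* **High-pass**: zero-phase 4th-order Butterworth at 0.5 Hz
  (forward–backward), applied to the continuous recording.
* **Power spectra**: Welch, 2-s Hann windows, 50% overlap, per untrimmed
  segment; baseline spectrum = arithmetic mean of the pre- and post-task
  baseline PSDs; decibel normalization bin-wise, then averaged over bands
  with inclusive edges. Band tables: θ 4–7, α 8–12, β 13–25, low γ 26–45,
  high γ 55–70 Hz for power/connectivity; θ 4–7, α 8–13, β 14–30, low γ
  31–45 Hz for CFC. The two tables are kept verbatim rather than
  reconciled. No 50-Hz notch: the 45–55 Hz gap between the γ bands already
  excludes line noise.
* **Connectivity filters**: least-squares linear-phase FIR, applied forward
  and backward (zero phase) via FFT convolution with the kernel's
  autocorrelation and odd-reflection edge padding (identical to `filtfilt`
  away from the ends, but tractable on 64 × 75 000-sample arrays). The
  design realizes a 15%-of-low-edge transition band (capped at half the
  bandwidth), lengthening the kernel beyond the 3-cycle minimum where
  needed; the two-pass passband gain is flat to < 1%. θ connectivity is
  filtered at 4–8 Hz per the worked recipe. Filtering and the Hilbert
  transform run on the continuous recording; segments are cut afterwards
  and trimmed by 200 ms per edge before the SI is computed.
* **CFC filters** are deliberately *short* (3 cycles of the low cutoff, 15%
  transition — the classic EEGLAB `eegfilt` design), normalized to unit
  gain at the band center. This is functional, not a shortcut: amplitude
  modulation at rate *r* puts sidebands at `f_high ± r`, outside a literal
  3-Hz pass band, and a sharp filter would remove the very power
  fluctuation whose phase the coupling index measures. The short kernel
  attenuates but retains those sidebands. The analytic branch of the FFT
  filter runs in single precision; phases and envelopes are estimated from
  tens of seconds of data, far above float32 resolution.
* **Synchronization index**: implemented as the *squared* mean resultant
  length of the phase-difference sequence, following the printed formula;
  the unsquared variant is exposed (`squared=False`) and is order-
  preserving, so either choice yields identical classifications. No second
  division by the series length is applied — the 1/n inside the resultant
  already provides the length normalization. For independent phases
  E[SI] = 1/n, which the tests verify by simulation.
* **CFC grids**: high centers 15–45 Hz in 3-Hz steps (3-Hz-wide filters),
  low centers 5–13 Hz in 2-Hz steps (3-Hz-wide); the per-pair value is the
  mean SI over grid points whose centers fall inside the labeled bands.
  Step sizes are exposed in `CFCGrid` since only the widths are pinned by
  the recipe.

## Montage, neighbors, ROIs

Channel positions come from the standard 10-05 montage shipped with MNE;
"neighbor" is defined by Delaunay triangulation of the 2-D
azimuthal-equidistant projection of the 64 used channels — standard and
parameter-free. One consequence worth noting: Fp1–Fp2 is *not* an edge
(Fpz lies between them), which is consistent with treating Fp1–Fp2 as a
long-range frontal–frontal connectivity pair in the ROI summaries. The
connectivity feature vector is each channel's mean SI over its non-neighbor
partners; with 64 channels and ~175 Delaunay edges this averages ~58 pairs
per channel. ROI-pair means (4 within + 6 between) are computed for
reporting, not classification, since 10 values cannot fill a 64-column
feature matrix.

## Decoding protocol

* **Classifier**: RBF-kernel SVM with kernel scale √P (P = 64 features,
  i.e. `gamma = 1/P`), box constraint C = 1, one-vs-one multiclass,
  features standardized by training-set mean/sd — the documented
  "medium Gaussian" preset convention, since no hyperparameters are given.
  No tuning is performed anywhere.
* **Splits**: stratified 80-10-10 train/cv/test; the cv and test folds each
  receive `round(0.1·n)` rows and the training fold the remainder, which
  yields 172/22/22 on 216 rows. The cv fold is held out and used only to
  report a secondary accuracy. Each of the 200 repetitions (50 in the
  scaled-down acceptance runs) uses a split seed derived from the master
  seed and repetition index via `SeedSequence`, so the whole protocol is
  reproducible from one integer.
* **Chance level**: per repetition, the labels of the train+cv rows are
  permuted (test labels untouched), the model refit, and test accuracy
  recorded. The actual and chance conditions share split seeds. A caveat
  documented because it is easy to misread: when the feature classes are
  strongly clustered, this null is not binomial — the permuted-label SVM
  still finds the cluster boundary and assigns its sign by the luck of the
  permutation, producing a wide, sometimes bimodal null. This is a property
  of the protocol, not a bug.
* **Grouped accuracies**: 4-class confusion matrices can be collapsed by
  modality ({1,2} vs {3,4}) or load ({1,3} vs {2,4}); collapsing can only
  merge error cells into correct ones, so grouped accuracy is never below
  4-class accuracy (property-tested).

## Statistics

One-way ANOVA compares accuracy across bands (df = k−1, N−k; 5 bands × 200
reps ⇒ 4/995); the bands × condition (actual/chance) two-way ANOVA uses the
full crossed design. The decomposition is delegated to `pingouin.anova`;
partial η² = SS_eff/(SS_eff+SS_err) and observed power are recomputed in
this package. Observed power follows the common post-hoc convention:
noncentral F with λ = F·df_eff at α = 0.05 (the central case is returned as
α exactly, because `scipy.stats.ncf` is numerically unreliable at λ = 0).
Accuracies enter untransformed, and no multiple-testing correction is
applied — both choices match the reporting style the tables follow.

## Problem sizes and numerical defaults

Default sampling rate is 256 Hz — enough to resolve the 70-Hz band edge
with margin — configurable down to 128 Hz, below which the high-γ band
cannot be computed (the band-average step then raises). Acceptance-level
parameter recovery runs at the full 18-participant design with 50 split
repetitions per condition; unit tests use 1–6 participants with 6–10 s
segments, which keeps the whole suite around seven minutes on one CPU.
EDF export quantizes to 16 bits over a per-channel symmetric range
(resolution ≈ range/32767, typically < 0.01 µV); round-trip tests assert
equality within that quantization.

## Known limitations

* The permutation null's heavy tails under strong class separation (above)
  make "N sd above chance" statements scale-dependent; the acceptance tests
  therefore compare means against the null's standard error and central
  95% band.
* The 64-column reduction of the pairwise connectivity matrix (per-channel
  mean over non-neighbor partners) is one reasonable resolution of an
  underdetermined description; rankings of bands are insensitive to it, but
  absolute feature values would differ under other reductions.
* ROI-pair connectivity summaries are unweighted means over unequal pair
  counts (e.g. 11 × 9 LF–LPO pairs vs 9 × 9 LPO–RPO).
* `read_recording` accepts EDF/BDF with a plain-text event sidecar;
  embedded EDF+ annotations are not parsed.
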