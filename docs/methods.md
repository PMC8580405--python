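# Methods

`hemianet` re-implements, as a tested and reusable pipeline, a
resting-state-EEG functional-connectivity analysis for patients with
hemianopia after occipital stroke: band-limited imaginary coherence
between atlas regions, graph-theoretic network measures under
proportional thresholding, lobe-level coherence profiles in a
lesioned/intact-hemisphere frame, responder classification from
visual-field change, and the accompanying statistics. Because the
original patient recordings are not publicly deposited, the package
ships a synthetic oscillatory cohort generator with known ground truth;
every estimation stage has a parameter-recovery test against what the
generator injected.

## Signal conditioning

Recordings are region-level (or channel-level) time series. Conditioning
follows standard resting-state practice: a 1–145 Hz order-4 Butterworth
band-pass and a 50 Hz notch (quality factor 30), both applied zero-phase
(forward–backward) because phase distortion would bias coherence;
polyphase resampling to 250 Hz; then common-average referencing.
Zero-phase IIR filtering attenuates the transition bands twice, so
re-conditioning is only a near no-op (< 1 % RMS change) for data that is
already band-limited — which conditioned EEG is; flat broadband input
loses a few percent of RMS per pass at the band edges. An
artifact-removal hook is provided for real data (ICA-based cleaning);
it is a no-op for synthetic input, which carries no blink or cardiac
components.

Epochs are 2 s long with 0.5 s of shared signal between consecutive
epochs (step 1.5 s), so a 300 s recording yields
`floor((300 − 2)/1.5) + 1 = 199` epochs. The overlap parameter is
explicit: users who prefer the 50 %-overlap reading can pass
`overlap_s = 1.0`.

## Imaginary coherence

For regions i and j with per-epoch Hann-tapered spectra `S_in(f)`
(0.5 Hz resolution at the standard settings), the coherency accumulated
over epochs n = 1..N is

    coh_ij(f) = Σ_n S_in(f) S*_jn(f) / sqrt(Σ_n |S_in(f)|² · Σ_n |S_jn(f)|²)

and the band connectivity weight is the mean over band bins of
`|Im(coh_ij(f))|`, with the absolute value taken per bin so phase leads
and lags cannot cancel. The square root in the denominator is required
for the estimate to be scale-invariant and bounded by 1. Instantaneous
(zero-lag) mixing of sources — volume conduction — produces a purely
real coherency, so the imaginary part rejects it; this is the property
the whole analysis leans on, and it is verified against a Monte-Carlo
null (see below). Seven bands are used: Delta 1–3, Theta 4–7, Alpha1
8–10, Alpha2 11–13, Beta1 14–21, Beta2 22–30, and whole-alpha 8–13 Hz;
band membership of a frequency bin is the closed interval. The diagonal
is zero by convention.

A finite number of epochs leaves a positive noise floor of order
1/√N even for independent signals (≈ 0.05 mean, ≈ 0.07 at the 95th
percentile for N = 199). `icoh_null_quantile` estimates this floor by
direct simulation of independent white-noise pairs; estimated
connectivity should always be judged against it.

## Graph measures

Node strength is the row sum of the full weighted connectivity matrix.
The binary measures operate on the graph obtained by keeping the
`round(p·K(K−1)/2)` largest-weight edges (proportional threshold,
p = 0.30 by default; ties at the cutoff broken by ascending row/column
index for determinism). On that graph:

* clustering `C_i = 2 t_i / (K_i (K_i − 1))`, zero for degree < 2, and
  the global coefficient is the node mean;
* the characteristic path length L is the node mean of each node's
  average shortest-path distance, averaging finite distances only; a
  disconnected node contributes its within-component average, a fully
  isolated node contributes 0 and is reported explicitly so the
  convention is auditable;
* betweenness centrality is the standard shortest-path count
  (unnormalized by default; a `(n−1)(n−2)/2` normalization switch
  exists).

Whether strength/centrality should be computed on the weighted or the
thresholded-binary matrix is not uniquely determined by the printed
formulas; the package fixes one convention (strength weighted, the rest
binary) and parameterizes it. Because the threshold depends only on the
rank order of weights, the binary measures are invariant under any
strictly monotone transform of the weights.

## Atlas and lobe coherence

The 90-region automated-anatomical-labeling table (45 regions per
hemisphere) ships as a packaged CSV — the single point of truth for lobe
membership. Cingulate, insular and subcortical regions map to "Other"
and are excluded from the four-lobe profile; the assignment of fringe
regions (e.g. Fusiform to Temporal, Paracentral lobule to Frontal) is a
documented package choice, as lobe boundaries are conventions rather
than facts. A reduced 10-region montage (2 hemispheres × 5 lobes) is the
default for simulation work.

Patients' matrices are relabeled into a lesioned/intact (LH/IH)
hemisphere frame so homologous regions align across patients with left-
and right-sided strokes; the mapping is an involution. Local coherence
is the unweighted mean over within-lobe region pairs; long-range
coherence is the mean over the block between a seed lobe and target
lobes (by default every other cortical lobe of both hemispheres). The
full profile therefore equals the block-size-weighted average of the
per-block values.

## Behavioral table and responders

The packaged 24-patient table (three stimulation groups of eight; high-
resolution-perimetry counts, reaction times, and perimetric visual-field
sensitivity FOV in dB at baseline, post-treatment and follow-up) is the
regression fixture: summary means reproduce the printed values exactly
under the table's display convention, which is truncation — not rounding
— to two decimals (25.4166… → 25.41). One printed reaction-time group
mean (gray, baseline: 0.51) does not equal the arithmetic mean of its
column (0.5225); RT means are therefore excluded from regression tests.
A responder is a patient whose FOV percentage change from baseline is
strictly positive; the comparison time point is a parameter (default
post-treatment; both post and follow-up give the 10/14 split on the
packaged table).

## Statistics

* Two-way mixed-design ANOVA (between: group; within: time), via
  pingouin, reporting F, dfs, uncorrected p, Mauchly's W and its p,
  the Greenhouse–Geisser epsilon, and the GG-corrected p (both dfs
  scaled by epsilon) for the within and interaction effects. The
  analysis value `p_report` uses the corrected p only when Mauchly's
  test rejects sphericity (p < 0.05); both are always emitted. With two
  within levels sphericity holds trivially (W = ε = 1). Note the
  GG-corrected p exceeds the uncorrected p only when F ≥ 1; for F < 1
  shrinking both dfs can lower it.
* One-way repeated-measures ANOVA for within-group time effects.
* Tukey–Kramer post-hoc comparisons from the studentized-range
  distribution with unequal-n standard errors and the pooled
  within-group MSE.
* Pearson correlation with the two-sided t-based p.
* Mann–Whitney U reported with its tie-corrected normal-approximation z
  (continuity correction off by default, switchable). The z-based p is
  an approximation to the exact permutation p; under heavy ties at very
  small n the two can differ substantially, which is why the tests
  compare them only for moderately tied n = 6 + 6 samples.
* No multiple-comparison adjustment is applied across region × band
  tests (the analysis is exploratory); a Benjamini–Hochberg switch
  exists for auditing.

## The synthetic cohort generator

No generative model for the patients' EEG is published, so every
simulator choice is an explicit package decision:

* **Oscillators.** Band components are Gaussian white noise band-passed
  to each canonical band with a zero-phase order-4 Butterworth filter —
  stationary, with analytically tractable spectra. Each region sums the
  six narrow-band components with a crude 1/f-like amplitude profile
  (Delta 1.0, Theta 0.7, Alpha1 1.0, Alpha2 0.7, Beta1 0.5, Beta2 0.35)
  plus broadband white noise. SNR is defined as total band-limited
  signal variance over broadband noise variance (default 4) and is
  recorded in every `GroundTruth`.
* **Coupling.** A coupled pair shares a band-limited source; the
  receiver sees it delayed (default: a quarter cycle of the band
  center, which maximizes |Im(coherency)|) and scaled by the coupling
  strength s, with its independent component attenuated to keep unit
  band variance — so the estimated band icoh approximates s, which is
  what makes the strength-ladder recovery test sharp. Zero-lag coupling
  is deliberately not expressible as a `CouplingSpec`; instantaneous
  crosstalk belongs to the mixing matrix.
* **Mixing.** A K × K matrix applied last (default: 5 % uniform
  leakage), emulating residual volume conduction. Ordinary coherence
  sees it; imaginary coherence must not — the module-level test compares
  both against the Monte-Carlo null.
* **Cohort effects.** Each subject carries a latent recovery score
  (zero at baseline; group mean plus a between-subject trait after
  treatment, with the treated combined-stimulation group receiving the
  nonzero means). The score drives both the behavioral FOV percentage
  change and the network architecture: an alpha-band path backbone over
  the montage (strength 0.6) keeps the thresholded graph connected with
  long paths; diametral "chord" couplings grow with recovery
  (0.1 + 0.45·score) while redundant short-range couplings fade
  (0.35 − 0.22·score). Recovery therefore trades local redundancy for
  long-range shortcuts, and the 30 %-thresholded alpha graph of a
  recovered subject has a shorter characteristic path length — this is
  the injected negative FOV ↔ CPL association (observed r ≈ −0.6 to
  −0.75 across seeds at the default settings). Separate switches inject
  the group × time coupling effects (an Alpha2 increase into the
  lesioned superior-occipital region at follow-up, a Delta-band
  interhemispheric occipital decrease and a Beta1 intact-
  occipital↔intact-temporal increase after treatment), and a latent
  node-strength metric with a configurable effect in within-subject SD
  units for power studies that do not need rendered EEG
  (`render_eeg=False`).
* **Defaults** mirror the study conditions: 3 groups × 8 patients,
  three time points, 5-minute recordings at 500 Hz, reduced 10-region
  montage. Everything is driven by one integer seed;
  identical (design, seed) pairs are bit-identical.

What the generator does **not** emulate: 1/f continuum noise (the
background is a band-limited mixture, not a power-law spectrum),
non-stationarity, artifacts (blinks, cardiac, muscle), realistic source
geometry or lead fields, and between-region delays other than the
configured coupling lags. Passing tests therefore demonstrate that the
estimation chain recovers known coupling structure under idealized but
fair conditions; they do not certify performance on real EEG.

## Calibration studies and problem sizes

The package validates its statistics by simulation, at sizes chosen to
keep the default test run desk-scale:

* type-I error of the mixed-ANOVA interaction under the null cohort
  design (3 × 3, n = 8): 1000 simulated cohorts, empirical size expected
  within 5 % ± 2 points (metric-level simulation, no EEG rendering);
* detection rate of the within-group time effect at the default injected
  strength effect (1.0/1.5 within-subject SD at post/follow-up, n = 8):
  100 cohorts; the analytic noncentral-F benchmark at these settings is
  ≈ 0.69;
* volume-conduction check: one 300 s mixed recording (199 epochs)
  against a 1000-rep Monte-Carlo null;
* coupling ladder {0, 0.2, 0.4, 0.6, 0.8}: three 120 s realizations per
  strength, Spearman ρ = 1 required on the five means;
* FOV ↔ CPL sign recovery: five cohorts of 24 subjects with 60 s
  recordings at 250 Hz (two time points), all five correlations required
  negative.

The acceptance script (`scripts/acceptance.py`) re-runs these studies
from scratch and writes the resulting numbers as JSON.

## Known limitations

* Graph measures on very sparse thresholded graphs can disconnect; the
  finite-distance CPL convention then changes the measure's meaning
  (flagged via `isolated_nodes`, but interpretation is the user's).
* The spectral estimator is a Hann-tapered FFT per epoch, not a
  multitaper; at 0.5 Hz resolution the narrow Delta band contains five
  bins, so its estimates are noisier than the beta bands'.
* The simulator's latent-metric table (used for power studies) is a
  statistical shortcut; it shares the effect sizes with the rendered
  EEG path but not its estimation noise.
* The behavioral generator produces plausible marginal distributions,
  not a validated joint model of perimetry and reaction times.
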