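# Methods

`pairlg` implements, end to end and without any recorded data, a
paired-stimulus local–global auditory ERP study: schedule generation,
synthetic multichannel EEG carrying the hypothesized component structure,
the preprocessing chain, group-level cluster statistics with threshold-free
cluster enhancement (TFCE), an individual-level classification-sensitivity
framework, and a sensor × epoch degradation sweep.  This note documents the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Stimulation paradigm

Each trial is a pair of 200-ms sounds with a fixed within-pair SOA of
350 ms.  The first sound is always the 1000-Hz standard S; the second is S
(S–S pair), the 1500-Hz frequency deviant F (S–F), or a spoken-numeral
train deviant T (S–T; tokens are identifiers `T1`–`T9`, audio is out of
scope).  A session holds 1380 pairs: an opening block of 30 S–S pairs
establishes the regularity and is excluded from analysis, leaving 1350
analyzed pairs split exactly 555 S–S / 540 S–F / 255 S–T (an 18.89% S–T
rate).  S–T pairs are separated by at least three intervening pairs, and
the run immediately preceding every S–T pair is homogeneous (all S–S or all
S–F, at least three pairs long), which defines that deviant's *global
context*; the default context split is 121 S–S vs 134 S–F.

Composition is enforced by exact counts, not Bernoulli draws: the printed
percentages are treated as count ratios, so every generated session
reproduces the composition deterministically.  Generation is constructive
rather than rejection-based: the shuffled context sequence fixes the order
of S–T pairs, each preceded by its minimum homogeneous run; surplus
same-type pairs are spread over the runs (and a shuffled tail) by a
multinomial draw.  All constraints then hold by construction, feasibility
is a closed-form check (`n_ss >= 3 * n_contexts_ss`, etc.), and generation
is O(n) with a single seeded stream — the active and passive variants of a
seed are identical, as the paradigm requires.

**Inter-pair jitter.**  The jittered 1000–1300 ms interval (50-ms grid) is
implemented as the silent gap between the *offset* of a pair's second sound
and the onset of the next pair.  With the 350-ms SOA and 200-ms stimuli the
expected pair period is 1700 ms and a full session lasts ≈ 39 minutes,
matching the paradigm's nominal ~40-minute duration; measuring the jitter
onset-to-onset would shorten sessions to ≈ 34 minutes, which is why the
offset-to-onset reading was adopted.

## Synthetic EEG

64 channels in the 10–20 layout of a standard 64-channel cap (including
M1/M2 mastoids and CPz), positions from the MNE 10-05 template, sampled at
1000 Hz.  The recording is expressed against the online reference CPz: each
component's per-channel gain has its CPz gain subtracted, and the mastoids
carry noise only, so the offline mastoid re-reference reconstructs the
"true" scalp distribution exactly as it would in a real recording.

**Components.**  Each evoked component is a Gaussian deflection (peak
latency, FWHM `half_width_ms`, signed peak amplitude) times a two-pole
synthetic topography — a Gaussian fall-off on the unit sphere around FCz
(frontocentral) or between CPz and Pz (centroparietal).  Defaults:

| name | latency (ms) | FWHM (ms) | amplitude (µV) | topography | attaches to |
|------|------|------|------|------|------|
| P1   | 76  | 30 | +2.5 | frontocentral | every stimulus |
| N1   | 124 | 36 | −4.0 | frontocentral | every stimulus |
| P2   | 184 | 48 | +3.0 | frontocentral | every stimulus |
| MMN  | 148 | 44 | −3.5 | frontocentral | second stimulus of S–F and S–T |
| P3a  | 248 | 60 | +5.0 | frontocentral | second stimulus of S–T |
| P3b  | 330 | 80 | +5.0 | centroparietal | second stimulus of S–T, active condition only |

Latencies are canonical auditory ERP values; amplitudes are free parameters
of the generator, set once in the upper part of the canonical per-component
ranges because topographic gain, 10-ms trial-to-trial latency jitter, and
the 1–30 Hz filtering jointly attenuate the effective single-channel evoked
amplitude by roughly half — with these values full-length sessions yield
the near-ceiling individual detectability this paradigm is designed for.
Between-subject variability applies one amplitude scale factor
(sd = 20% of the mean) and one latency shift (sd = 5 ms) per component per
participant, shared across that participant's two sessions.

**Noise.**  Ongoing activity is channel-wise 1/f^α noise (α = 1, broadband
sd 8 µV before filtering) synthesized by FFT spectral shaping, plus a
posterior-weighted 10-Hz alpha rhythm (3 µV) with random per-channel phase,
mixed once with the neighbor average (weight 0.5) to induce realistic
spatial correlation (the realized neighbor correlation is approximate, not
calibrated).  Optional square-pulse excursions of ±150 µV emulate gross
artifacts for rejection testing; the default artifact rate is 0.  The noise
model deliberately omits ocular/muscle sources (ICA is out of scope), so
passing tests validate the pipeline's statistics, not artifact robustness
on real recordings.

Per-component jitter streams are keyed by (seed, component name), making
the simulation exactly additive over the component set under a shared seed
— the property the simulator tests exploit.

## Preprocessing

Sequential zero-phase FIR filtering in the stated order — 50-Hz notch,
1-Hz high-pass, 30-Hz low-pass (MNE defaults for transition bandwidths) —
then re-reference to the M1/M2 mean, then polyphase down-sampling to 250 Hz.
Zero-phase FIR was chosen because component latency is load-bearing for
every downstream window.

Five contrasts are cut into baseline-corrected epochs (half-open windows on
the 4-ms grid):

* **P1N1P2** — first S of each analyzed pair, −100..350 ms (baseline
  −100..0) vs the pre-stimulus resting state.  The RS epoch is the
  −450..0 ms interval with a −450..−350 ms baseline; it is represented as
  the same −100..350 window around a virtual lock 350 ms before S onset, so
  both classes share one time axis and feature geometry.
* **Local_SF / Local_ST** — second-stimulus deviant vs the first S of the
  same pair, same 450-ms geometry.
* **Global_SS_ST1 / Global_SF_ST2** — T of an S–T pair vs the second
  stimulus of the immediately preceding context pair, −100..800 ms.

Rejection drops any trial exceeding ±100 µV on a non-mastoid channel and is
*matched* within a contrast's aligned trial pairs (a rejection in either
member drops both), so condition counts stay balanced.  Matching is applied
to all five contrasts — the global contrasts pair each T epoch with its
context-pair epoch — because balanced counts are what the matching exists
to guarantee.

## Group-level cluster statistics

Per-participant condition-averaged waveforms enter a paired test per
(channel, sample).  The enhanced statistic is TFCE with the canonical
parameters E = 0.5, H = 2, dh = max|map|/50, computed per polarity on
absolute values and re-signed; spatiotemporal connectivity couples channel
adjacency (Delaunay triangulation of 2-D projected positions, edges pruned
at 1.5× the median length) with temporal adjacency of consecutive samples.
The null distribution is the maximum |TFCE| over the map under random
sign-flips of participant difference waveforms (two-tailed by construction),
with the observed labeling included; when all `2^n` sign patterns fit the
permutation budget the null is enumerated exhaustively, which matters at
desk-scale cohorts where the attainable p floor is `2/2^n`.  Points with
p ≤ α = 0.05 form the significant mask, which is reduced to reported
clusters by two post-hoc filters applied in this order: at least two
mutually adjacent channels must co-occur at some time point, and the
cluster must persist ≥ 20 ms.  Representative summaries restrict clusters
to a named electrode (Fz for early/local effects, Pz for global effects).

**Variance smoothing.**  By default the mapped statistic is the
variance-smoothed pseudo-t, `m / sqrt((v + v0)/n)` with `v0` the median
cellwise variance of the map (recomputed per permutation, so the statistic
is one fixed function of the signed data).  With small cohorts the raw
paired t produces near-zero-variance spikes whose TFCE dominates the
max-statistic null and destroys sensitivity; the pseudo-t removes them
while leaving calibration intact — the suite verifies the family-wise
false-positive rate empirically on 200 null cohorts.  `var_smooth=False`
restores the raw t.  `paired_t_map` itself is the exact paired t (with
zero-variance cells set to 0 when the mean is 0, else capped at ±1e6 with
a warning).

## Individual-level sensitivity

Per contrast and participant, trials are averaged into 50 non-overlapping
blocks of `floor(n/50)` consecutive trials (remainder dropped from the end;
fewer trials than blocks fall back to single-trial samples with a warning),
cropped to the decode window (0–300 ms for the early complex and local
effects, 0–400 ms for global effects), and classified with a linear
maximum-margin SVM (default regularization) under stratified fivefold
cross-validation, features standardized inside each training fold.  The
dual permutation framework runs `n_iter` iterations with true labels
(re-randomized fold partition each iteration — the only stochastic element
under true labels) and `n_iter` with freshly permuted labels (folds also
re-randomized); a component is detected when the mean true-label accuracy
exceeds the 95th percentile of the null accuracies, and the empirical p
value (fraction of null ≥ observed mean) is reported alongside.  The
active-vs-passive comparison classifies session condition from the
global-deviant T epochs with the same machinery.

For speed the linear kernel is evaluated as a precomputed Gram matrix of
the fold-standardized features; this is algebraically the same optimization
problem as the pipeline `StandardScaler + SVC(kernel="linear")` and was
verified to produce identical fold accuracies on shared fold assignments.

## Sensor × epoch sweep

The 4 × 4 factorial crosses nested sensor subsets (8 ⊂ 16 ⊂ 32 ⊂ 64,
defined once to resemble realistic 10–20 caps, mastoids never enter
features) with epoch fractions 0.25/0.5/0.75/1.0.  Epoch subsampling takes
the first ⌈fraction·n⌉ epochs in temporal order, emulating a shorter
recording (a random mode is deliberately not the default).  At the 0.25
fraction the epoch budget cannot fill the blocks, so raw epochs serve as
classification samples without block averaging.  Each configuration is
scored by repeated fivefold CV (500 repeats at full scale), averaged over
participants.  Spearman rank correlations relate the 16 configuration means
to epoch fraction and to sensor count; 95% CIs come from a percentile
bootstrap that resamples *participants* (not grid cells), re-means the
grid, and recomputes both correlations per replicate.  Constant grids
report the correlation as undefined.

## Orchestration, seeding, problem sizes

`run_study` drives the whole pipeline from one `StudyConfig`; every random
stream derives from the master seed by hashing (seed, stage, participant),
so stages and participants are statistically decoupled and re-running a
configuration reproduces every number exactly (a manifest records the
config, its hash, and the seeds).  Two fixture scales support fast
end-to-end runs: `unit` (2 participants, 106-pair sessions, 3-fold CV,
100 permutations/iterations) and `smoke` (6 participants, 300-pair
sessions, 200 permutations, 100 iterations).  The analysis scripts and the
acceptance script run at these desk scales; full-scale settings (30
participants, 1380 pairs, 1000 permutations/iterations, 500 CV repeats)
are the configured defaults and run unchanged, just longer.  At desk scale
the attainable detection rates and cluster extents are naturally weaker
than at full scale — block sizes shrink from ~26 trials to ~1–6 — so
scaled-down results should be read as qualitative validations of the
machinery, not as reproductions of full-scale effect sizes.

## Known limitations

* Synthetic topographies are two-pole gain maps, not forward-model
  projections; claims are sensor-level only.
* The noise model has no ocular/muscle artifacts, no non-stationarity, and
  only approximate spatial correlation.
* The RS baseline interval (−450..−350 ms before S onset) can overlap the
  preceding pair's late activity at short inter-pair intervals; this
  mirrors the paradigm definition and is left as is.
* Bad-channel interpolation and ICA are out of scope; a real-data entry
  point would insert them between loading and filtering.
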