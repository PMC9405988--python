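# Methods

`tvdfc` analyzes multichannel EEG around temporally localized emotional
events: a subject watching naturalistic videos clicks at the moment of an
emotional feeling, labels the click with one of 24 emotion words, and
rates it on six self-assessment scales (valence, arousal, dominance on
1–9; liking, familiarity, relevance on 1–5). The pipeline asks three
questions. In which frequency band do the functional networks of
different emotions separate best? Does the moment-to-moment variability
of those networks predict the rated dimensions of the experience? And
which electrodes act as network hubs?

## Epochs, bands, segments

Event epochs run from 6 s before a click to 1 s after it (7 s; 1750
samples at 250 Hz). Events whose 7-s windows overlap within a subject
are dropped entirely — both members of an overlapping pair — mirroring
the exclusion rule of the study design this pipeline reproduces. Windows
are half-open `[start, end)`, so windows that merely touch do not count
as overlapping. Baseline epochs are 7-s windows drawn uniformly at
random (via the order-statistics spacing construction, so the
non-overlapping layout is exactly uniform) from the 10–70 s span of the
80-s eyes-open baseline; at most eight such windows fit, and the
pipeline caps the per-subject baseline count at that packing bound.

All filtering is zero-phase (forward–backward) Butterworth, applied as
second-order sections. We use order 6 per direction: the 1–40 Hz
wideband filter then passes less than 5% of the RMS of a 50 Hz tone
(order 4 passes 9%), which matters because line noise sits immediately
above the gamma edge. Zero-phase filtering is essential here because
downstream phase-locking estimates must not inherit filter phase
distortion. The six analysis bands are delta 1–4, theta 4–8, alpha
8–12, lower beta 12–20, upper beta 20–30 and gamma 30–40 Hz. The band
filter bank is not exactly complementary; on broadband noise the sum of
the six band signals reconstructs the 1–40 Hz signal with a relative L2
error of about 15% (crossover leakage), and tests document a 25% bound.

Each 7-s epoch is cut into 250-sample windows advanced by 175 samples:
nine segments, the last covering samples 1400–1650. The printed segment
table of the source design uses this 175-sample step (30% overlap) even
though its prose says "33% overlap"; the printed boundaries are taken as
authoritative. The final 100 samples of the epoch fall outside every
window by construction.

## Phase-locking value

Instantaneous phase is the argument of the analytic signal (Hilbert
transform) of the **full** band-limited epoch, computed before
segmentation; computing it per 250-sample segment would put Gibbs-type
edge distortion inside every window. The first and last 125 samples of
the epoch remain edge-affected and are flagged as metadata
(`PLVTensor.edge_samples`). For channels a, b and one segment of N=250
samples,

    PLV = | (1/N) Σ_t exp(i (φ_a(t) − φ_b(t))) |  ∈ [0, 1].

PLV is averaged over time within a segment for a single event — not
across trials — because the pipeline needs one network per (event,
segment) for the temporal-variability statistic and the event-level
regression. Channel pairs are indexed lexicographically (i < j in
recording channel order) and that order is persisted in every output.

## Significance: max-statistic permutation test

For each (band, segment, emotion group), per-pair PLVs of the group's
events are contrasted with baseline-epoch PLVs using a two-sample
pooled-variance t statistic (the t normalization prevents high-variance
pairs from dominating the maximum). Both conditions come from the same
subjects with unequal counts, so "related samples" is implemented as
within-subject exchange of condition labels, preserving each subject's
per-condition counts; baseline epochs of subjects with no events in the
group are excluded, and a subject present in only one condition is an
error. Each of N permutations (default 1000, seeded) records the
maximum |t| over all pairs; the adjusted p-value of a pair is the
add-one tail proportion of permutation maxima at or above its observed
|t| (minimum attainable p = 1/(N+1)), and a pair is significant when
p_adj < α = 0.01. The single-threshold critical value is the (c+1)th
largest permutation maximum with c = ⌊αN⌋. The test is two-sided on
|t| since both hyper- and hypo-synchrony relative to baseline are
plausible. Empirically (acceptance suite, 200 replicates of a 16-channel
global null), the family-wise error at α = 0.01 is ≈ 0.02.

## Emotion grouping

The 24 labels are pooled into 8 groups by complete-linkage agglomerative
clustering of their mean (valence, arousal) positions, followed by a
greedy rebalancing pass that moves boundary labels from groups whose
instance count exceeds (1 + tolerance) × (total/8) — tolerance defaults
to 25% — to the nearest group below the even share, accepting only moves
that reduce total imbalance. The procedure is deterministic for a fixed
input ordering. Group ids 1–8 are assigned by ascending mean valence.
The source criteria name proximity and balance but no algorithm; this
realization was chosen for determinism and auditability.

## Band selection: Gcst

Per (band, segment), each group's significant pairs form a weighted
multi-hot connectivity vector (group-mean PLV where significant, zero
elsewhere). Euclidean distances between the 8 group vectors give
C(8,2) = 28 values per segment, pooled (averaged) over the nine segments
into 28 per-band distances; the grand mean over all bands and pairs is
the global threshold Gcst. Each band's 28 pooled distances are tested
against Gcst with a one-sample t-test (alternative: mean > Gcst,
df = 27), Bonferroni-corrected across the six bands; Cohen's d is
(mean − Gcst)/sd. When at least two bands are significant the top two
are compared with a paired t-test matched by group pair. The reference
analysis of the 40-subject study reports Gcst = 8.24 and upper beta
t(27) = 3.28; those magnitudes require the real dataset and are
documentation only — desk-scale synthetic runs produce much smaller
distances. A band in which no pair is ever significant has zero-variance
distances; the pipeline records it as not-selected rather than erroring.

## Temporal variability (tvDFC)

For each event on the selected band, its nine per-segment PLV vectors
are masked by the event's group's per-segment significance masks, and
tvDFC is the mean of the eight Euclidean distances between consecutive
segment vectors. The unit is per-event (not per-group) because the
regression pairs tvDFC with event-level ratings under subject random
intercepts; the source design does not state the unit and this is the
reading consistent with that regression.

## Regression models

`scale ~ tv + (1 | subject)`, fitted by REML (statsmodels MixedLM), with
Wald inference on the slope and CI = β ± 1.96·se. Both predictor and
outcome are z-scored before fitting: the reference slopes (≈0.5 on a 1–9
scale) are only plausible standardized, so the package reports
standardized slopes throughout. Satterthwaite-style fractional degrees
of freedom are not available in the fitting backend; p-values use the
large-sample normal reference and the recorded `df = n_obs − 2` is
descriptive. At the zero-variance boundary the model reduces exactly to
OLS; `fit_scale_on_tv(..., re_variance=0.0)` computes that reduction in
closed form and tests verify agreement with OLS to 1e−6. The companion
check `high_tv ~ arousal × dominance + (1 | subject)` binarizes tv at
the within-dataset median (the source does not define "high") and fits a
random-intercept logistic model by variational Bayes
(BinomialBayesMixedGLM), the mixed-logit estimator available in the
environment; its "p" is the two-sided normal tail of posterior mean/sd.
The variational fit consumes the legacy global NumPy RNG, which the
function pins from its seed argument and restores.

## Hubs

Significant connections of the selected band are pooled over segments
and groups into one weighted adjacency (a pair's weight is the mean of
its group-mean PLV over the networks where it is significant; weighted
by default, with binarization available upstream by thresholding).
Eigenvector centrality is computed by shifted power iteration (shift =
max weighted degree, handling bipartite spectra) on the largest
connected component, scores ≥ 0 with unit Euclidean norm and zeros off
the component; tests verify agreement with dense eigendecomposition to
1e−8. Significance uses 10,000 Erdős–Rényi graphs with the observed
connection probability: a channel is a hub when its centrality exceeds
the 95th percentile of the pooled null centrality distribution. The
pooled-null reading is the simplest defensible interpretation of "less
than a 5% chance of being randomly selected"; a stricter alternative
(per-graph maximum-centrality null) is noted in the code.

## Synthetic data generator

The generator emulates the study design, not real EEG. Defaults are the
study's conditions: 40 subjects, 250 Hz, an 80-s baseline, 10 events per
subject (~420 events total before exclusions), 24 labels in 8 latent
valence–arousal groups, ratings on the 1–9 / 1–5 scales (clipped after
noise). Channels default to 32 with 10-10 montage labels — desk-scale
rather than the study's 128, and configurable. Each channel is a sum
over the six bands of narrowband oscillations (carrier at band center
with smooth random frequency modulation confined to the band) plus
1/f-shaped Gaussian background noise at EEG-like per-band amplitudes.

Coupling: a configured (source, target) pair in a band locks the
target's band phase to the source's plus a constant lag plus von Mises
jitter drawn at 0.1-s nodes and linearly interpolated, with
concentration k = 10κ/(1−κ) for coupling strength κ ∈ [0, 1] (κ = 1 is
exactly zero jitter). The node-level expected PLV is I₁(k)/I₀(k), which
is monotone in κ; interpolation smooths the jitter so measured PLV sits
slightly above that value, and cross-band leakage plus background noise
keep even κ = 1 pairs marginally below 1 (≈0.93–0.99 per segment).
Group-restricted couplings are active only during the epochs of events
in those groups, with 0.2-s crossfades at window edges.

Ground truth for the regression: each event carries a latent variability
index v ~ N(0,1) (clipped to ±3). The index modulates how deeply the
pair's κ dips on alternating segments of that event's epoch (injecting
true temporal variability) and enters the generated arousal rating as
`group offset + tv_slope · v + noise`. Regressing arousal on v recovers
`tv_slope`; regressing on *measured* tvDFC recovers an attenuated
positive slope, as with any noisy proxy. The event-level simulator used
for parameter-recovery checks (`simulate_tv_records`) works on the
standardized latent scale directly, with subject-intercept and noise
variances chosen to make the latent outcome unit-variance, so the fitted
standardized slope targets the nominal β exactly and clipping is
negligible (<1%).

What the generator does **not** emulate: volume conduction and source
leakage (couplings are channel-level), artifacts (blinks, EMG), montage
geometry, non-stationary background spectra, and rating response styles.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the declared signal model, not
robustness to real-EEG confounds.

## Problem sizes and numerical choices

Desk-scale simulation sizes used by the test and acceptance suites, as
the package's own choices: FWER calibration uses 16 channels, 6 subjects
× (5+5) epochs, 500 permutations, 200 replicates; band-selection
recovery uses 20 pipeline runs at 6 subjects × 16 events, 8 channels,
200 permutations; regression recovery uses 40 subjects × 10 events.
Permutation defaults are 1000 in production configs. Power iteration
stops at an update norm of 1e−13 (cap 10,000 iterations). Filter-bank
reconstruction tolerance is documented at 25% relative L2. The pooled-
variance denominator is floored at 1e−300 only to avoid 0/0 in permuted
all-equal columns; observed degenerate samples raise errors instead.
All randomness descends from a single root seed expanded per stage via
SHA-256, so identical configs reproduce byte-identical TSV/JSON outputs.

## Known limitations

- The reference study's headline numbers (Gcst = 8.24, t(27) = 3.28,
  β = 0.514, 15 named hubs) depend on its 40-subject, 128-channel
  dataset and are not reproducible from synthetic desk-scale runs; the
  package reproduces the design arithmetic exactly and the statistical
  behavior distributionally.
- The max-stat test assumes within-subject exchangeability of event and
  baseline epochs under the null; slow drifts violating this are not
  modeled.
- The variational mixed-logit posterior sd can understate uncertainty
  relative to full-likelihood fits; the interaction check is a null
  screen, not a precise effect estimate.
- Hub inference conditions on the estimated network; uncertainty in the
  significance masks does not propagate into the hub null.
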