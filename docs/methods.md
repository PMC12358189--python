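# Methods

This note documents the models, rules and numerical choices behind
`dcblock`, and what its synthetic validation does and does not establish.

## Synthetic session model

A *session* is one animal × one stimulus modality: `n_pre_sets` pre-DC
recording sets, four during-DC sets covering {500, 1000} µA × {cathodic,
anodic centre} in pseudorandom order, and `n_post_sets` post-DC sets at a
fixed spacing (default every 5 min to 45 min).  The DC waveform itself
(10 s ramps around a 100–110 s plateau) is carried as metadata: recording
within a set happens entirely on the plateau, so the condition is constant
per set.

**Spike trains.**  Each unit is an inhomogeneous Poisson process:
a homogeneous spontaneous component (default 5 spikes/s) plus per-stimulus
evoked spikes whose count is Poisson with modality-specific mean and whose
latencies follow a truncated (mixture) normal:

| modality | evoked mean/stimulus | latency model | support (ms) |
|---|---|---|---|
| tactile | 1.5 | N(8.31, 1.2²); pain groups mix a second mode at 16 ms | 0–40 |
| noxious press | 8 | N(90, 80²) truncated | 0–500 |
| proprioceptive | 6 | 0.5·N(50, 30²) + 0.5·N(250, 40²) | 0–400 |
| noxious thermal | 35 | N(1150, 150²), plus uniform sustained tail (mean 25) | 800–1500 / 1500–4500 |

Stimulation paradigms: two stimuli at 20 s spacing for noxious thermal,
sets of 50 at 1 Hz otherwise.  Trial segments span −1 to +4.5 s (thermal)
or −1 to +1 s.  Pain-model groups carry a ×1.3 evoked-count elevation
(baseline hypersensitivity) and the tactile mixture weights are chosen so
the mixture means equal the reported group means (10.85 ms neuropathic,
10.41 ms inflammatory).  Between-unit and between-animal evoked gains are
log-normal (σ = 0.25 and 0.10).  A 1.5 ms absolute dead time is enforced on
every train *before* any DC effect, so clean units can never trip the ISI
contamination rule and the thinning identity below is exact.

**DC effect.**  During DC, every spike inside a response window is
independently deleted with the condition's reduction probability *r*, so
the expected windowed count is exactly (1 − r) times its pre-DC value; this
holds for spontaneous spikes that happen to fall inside the window as well,
which is what makes the percent-reduction target an exact identity rather
than an approximation.  Spontaneous firing outside the windows is scaled up
by a small gain (default 1.10) via superposed Poisson spikes that respect
the dead time.  Default *r* values per group × modality are the lower
bounds of the reported percent reductions (e.g. thermal pain 0.705, tactile
neuropathic 0.576, tactile inflammatory 0.305 at 1000 µA only,
proprioceptive naive 0.290, sustained thermal pain 0.564); conditions with
no reported reduction use r = 0.

**Recovery kinetics.**  Each unit draws a block-release time
τ ~ Exponential with median equal to its modality's half-life (defaults:
tactile 2 min, press 8 min, thermal 20 min).  Post DC the unit remains
fully thinned (probability *r*) until τ and is unaffected afterwards, so
the *population-average* thinning decays as r·2^(−t/half-life).  All-or-none
release was chosen over graded per-unit decay deliberately: with graded
thinning, any response surviving at ≳15% strength is already statistically
detectable at 50 trials, recovery becomes purely detection-limited, and the
observed modality ordering of recovery times cannot arise.  Per-unit
release with an exponential population law preserves the half-life
semantics and reproduces the ordering (tactile < press < thermal, with a
few thermal units not recovering within the 45 min horizon).

**Templates and rendering.**  Waveform templates are biphasic 3-channel
footprints, 48 samples (1.6 ms) at 30 kHz: an asymmetric Gaussian trough
(rise 1.5–4, fall 2–7 samples), optional pre-spike positivity and a slower
rebound; the dominant channel (any of the three — units sit at different
depths) peaks at snr × noise_sd and flanks are attenuated by ≥ 40%.
Candidates are redrawn until all pairwise normalised cross-correlations are
below 0.75 (well under the 0.95 distinctness contract), because the
clustering stage must separate units whose within-cluster spread is
dominated by band-limited noise.  Rendering is linear superposition of
templates on Gaussian noise; overlapping spikes simply add.

## Analysis pipeline

**Filtering** is a 4th-order Butterworth band-pass (300–5000 Hz) applied
forward–backward (zero phase).  **Detection** median-centres each channel,
thresholds at θ = 4.5·median(|v|)/0.6745, enforces a 1 ms lockout within
the 3-channel group, and aligns each event to the trough on a ×4 upsampled
trace before extracting the 0.6 + 1.0 ms snippet on the aligned grid; the
sub-sample alignment exists because alignment jitter otherwise inflates
within-cluster variance more than the noise itself.  Channel triples are
ranked by an evoked-energy score (mean over trials of post- minus
pre-trigger RMS, summed over the triple); this automates a step done by eye
in practice and the score definition is this package's own.

**Sorting** concatenates the three channels of each snippet, keeps the
first 10 principal components (or fewer at 95% variance), and runs k-means
with 10 restarts for each k in 2–8, choosing k by maximum mean silhouette;
below silhouette 0.3 (or with too few events) everything stays in one
cluster.  The ISI rule is implemented with the inclusive comparisons
exactly as printed (flag iff fraction of ISIs ≤ 1 ms is ≥ 0.01): a flagged
cluster is split k = 2 in the *template* PC space (the basis is reused, not
refit), children inherit the reiteration count, and a lineage still flagged
after 4 reiterations is excluded.  Note that with a 1 ms detector lockout,
detected event streams cannot contain sub-millisecond ISIs, so on the
voltage path the rule mainly guards spike-time-level inputs and
configurations with a shorter lockout.  Transfer projects events onto the
template basis and assigns to the nearest non-excluded centroid, leaving
events beyond 3× the cluster's 95th-percentile template distance
unassigned.  Modality labels come from the template paradigm; a non-tactile
unit that also passes the evoked criterion on the tactile probe becomes
`multimodal_excluded` (the rule is one-directional, as printed).

**Windows.**  Latency histograms tile the trial span with a bin edge at 0
(bin widths 50/10/1/10 ms for thermal/press/tactile/proprioceptive); the
baseline is the mean per-bin frequency over the pre-stimulus span.  The
derived window runs from the first to the last post-stimulus bin with
frequency ≥ 1.5× baseline.  "Rounded away from the peak by one significant
digit" is read as: drop the last significant decimal digit of the edge (in
ms), rounding toward −∞ for edges left of the peak and +∞ for edges right
of it — 38 → 40, 1480 → 1500, 850 → 800, 2 → 0; a single-digit edge rounds
down to 0.  This reading reproduces every published window timing from
plausible crossings.  The pipeline defaults to the fixed canonical windows
for comparability; derived mode recomputes the post window from data.  All
counting is half-open [start, end), and relative times are rounded at the
sub-nanosecond level so whole-millisecond boundaries behave exactly.

**Evoked criterion.**  Paired one-sided t-test on per-trial (post − pre)
differences; "significantly more" fixes the direction and pairing is the
natural per-trial structure (a two-sample variant is available).
Zero-variance differences are decided by sign.  Under a Poisson null with
50 trials the empirical type-I error is ≈ 0.05.

**Mixed models.**  Windowed spike totals are modelled on the raw count
scale with a Gaussian LMM fit by REML (statsmodels MixedLM): animal is the
grouping factor with a random intercept and unit enters as a variance
component nested within animal.  EMMs are computed on a reference grid that
crosses the focal factor with the observed combinations of the other
categorical fixed effects, holding numeric covariates (such as the
pre-stimulus count) at their means; contrasts use residual degrees of
freedom with studentized-range (Tukey) adjustment.  Satterthwaite degrees
of freedom are not available in this stack; with the cell sizes used here
the residual-df approximation is conservative at third-decimal precision,
and one test cross-checks the EMMs against an independent reference LMM
implementation (lmer/emmeans via Rscript) on simulated data.  Singular
(boundary) fits are flagged, not hidden; hard non-convergence raises.

**Dip test.**  The dip statistic — the maximum distance between the
empirical CDF and the nearest unimodal CDF — is computed with the
greatest-convex-minorant / least-concave-majorant algorithm, floored at its
sample-size minimum 1/(2n).  The implementation is validated in the test
suite against an exact oracle that solves the min–sup problem by linear
programming over convex–concave piecewise-linear CDFs (tractable at small
n).  p-values come from a uniform(0, 1) bootstrap null (default 2000
draws), cached per sample size so calibration studies are cheap.

## Problem sizes and tolerances

Reduction studies use 40 thermal units (8 animals × 5; 5 pre-DC sets of 2
stimuli) or 60 units (6 × 10; 2 pre-DC sets of 50 stimuli) per condition —
enough that the EMM-ratio estimate lands within ±3 percentage points of the
generator truth with margin.  Sorter validation uses 20 seeded sessions of
3–6 units at snr 8 on a shared 3-channel footprint (noxious-press
paradigm, whose latency spread avoids systematic spike collisions within
the detector lockout).  Dip calibration uses n = 200 with 2000 bootstrap
draws.  The evoked-classifier calibration uses 5000 null units × 50 trials.

## Limitations

The generator draws white Gaussian noise (no correlated background or line
noise), renders no DC-onset artifacts, and its evoked profiles are
stationary within a session (no drift, no electrode movement), so passing
tests demonstrate correctness of the analysis rules and estimator
calibration under the assumed statistical structure — not robustness to
every pathology of real recordings.  Multi-animal cohorts are generated as
independent single-animal sessions.  The mixed model is Gaussian on counts
(as in the original analysis), which is mis-specified for very low-count
windows; the EMM ratio remains unbiased in expectation but its SEs inherit
the approximation.  The coarse-bin monotonicity of derived windows holds
for gentle response flanks and can fail for flanks steep relative to the
bin width; the test suite exercises the gentle regime.
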