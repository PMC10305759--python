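# Methods

## The analysis model

Resting EEG is modelled as a sequence of quasi-stable scalp fields: at any
instant the (average-referenced) channel vector x(t) ∈ ℝ¹⁹ is proportional
to one of K microstate maps mₖ, up to polarity and additive noise.  All
map arithmetic is therefore polarity- and scale-invariant: maps are
zero-mean unit vectors, similarity is |Pearson r| across channels (equal
to |cosine| for zero-mean vectors), and clustering assigns by r².

**GFP and peaks.**  Global field power is the population (÷ n) standard
deviation across channels per sample.  Topographies are sampled at strict
local GFP maxima, found within contiguous data segments only, never across
the splices introduced by eyes-closed segment selection.

**Modified K-means.**  Peaks are assigned to the cluster maximizing
squared spatial correlation; each cluster map is re-estimated as the top
eigenvector of the GFP²-weighted outer-product sum of its members (the
classical sign-free update: scaling the normalized peak maps by their GFP
makes the eigen-update exactly maximize the GEV objective, which is
asserted to be non-decreasing per iteration).  Empty clusters are reseeded
with the worst-explained peak.  Defaults: 10 restarts, 100 iterations,
GEV tolerance 1e-6.  The best restart receives a Hartigan-style
refinement: because the objective of an assignment with optimal maps is
Σₖ λ_max(Cₖ), single-point moves are scored by rank-1 eigenvalue
re-evaluations and applied while they improve the objective.  This escapes
Lloyd fixed points that peak-seeded restarts cannot leave (verified
against exhaustive assignment search on small instances).

**Model selection.**  The silhouette score under d = 1 − |r| is computed
for each K from a modified-K-means fit; K = 4 wins on cohorts generated
from four maps, matching the classical A–D parcellation.

**Two-level clustering and labeling.**  Each subject contributes K maps
fitted to its own GFP peaks; the concatenated subject maps are clustered
again for the group maps.  Group maps are labelled A–D by Hungarian
matching (maximizing total |r|) against deterministic canonical templates;
in the full pipeline only control-group subjects inform the group maps,
which are then backfitted to every subject, controls included, so all
groups are measured against the same reference topographies.

**Backfitting and smoothing.**  Every sample takes the label of the
best-|correlation| reference map; zero-variance samples inherit the
previous label (or the first valid one at a segment start).  Temporal
smoothing uses a centred sliding majority vote with full window
round(82 ms × rate) samples (21 at 256 Hz), votes counted within the
segment only, incumbent label winning ties, iterated to a fixed point
(≤ 10 passes).  A strictly alternating two-class sequence is a fixed
point of that vote (every sample holds a one-vote self-majority), so a
final pass merges any run shorter than ⌈w/2⌉ samples into its longer
neighbour (shortest first, ties to the left).  Smoothing therefore
lengthens mean durations by construction — it absorbs sub-window
sojourns — while leaving coverage essentially untouched; group contrasts
are computed on identically smoothed data, so the lengthening is common
mode.

**Temporal statistics.**  Runs are maximal same-label spans within
segments.  occurrence(k) = runs/s, coverage(k) = % of samples,
mean duration(k) = mean run length in ms; absent classes get occurrence
and coverage 0 and a missing (NaN) duration that propagates as missing.
The identities Σ coverage = 100 % and occurrence × duration(s) =
coverage(fraction) hold exactly and are property-tested.  Runs touching a
segment edge count normally (truncation bias is negligible for recordings
much longer than a sojourn).  C/D ratios divide class-C by class-D values
and are missing (with a warning) when class D is absent.

## Group inference

The BEST model: each group t-distributed with its own μ and σ and a
shared ν; priors μ_g ~ Normal(pooled mean, 1000·pooled SD),
σ_g ~ Uniform(pooled SD/1000, pooled SD·1000), ν − 1 ~ Exponential(29).
The effect size d = (μ₁−μ₂)/√((σ₁²+σ₂²)/2) is summarized by its posterior
mean, 90 % HDI (shortest sorted-window interval) and P(|d| > 0.1), the
probability of lying outside the region of practical equivalence; a
difference is declared when that probability reaches 0.95.  ROPE bounds,
threshold and HDI mass are configuration-exposed.

Sampling uses an affine-invariant ensemble (16 walkers, differential-
evolution + snooker moves — measured ~2.5× shorter autocorrelation than
the stretch move on this posterior), 1000 warm-up steps and 10 000 pooled
posterior draws by default.  Convergence is gated on split-R̂ over walker
chains < 1.05 — a practical bound for short correlated walker chains;
fits above it warn and carry `converged=False`, and acceptance fraction
and a crude ESS are always reported.  No multiple-testing correction is
applied across the comparison grid by default (mirroring the analysis
protocol); the grid output carries everything needed to apply one.

The frequentist companion fits value ~ group + age + sex by OLS and
reports the Type II F-test for group, Levene (median-centred) and
per-group Shapiro–Wilk.  In the pipeline it runs across disease groups
only, as covariate-balanced controls are generally unavailable in
retrospective cohorts.

## The synthetic-data generator

The generator emulates eyes-closed resting 19-channel EEG and nothing
more:

* **Sequences** — semi-Markov: sojourns gamma-distributed with shape 2
  (avoiding the excess of very short states an exponential would give)
  and class-specific means, default 80 ms; the next class is drawn from
  occurrence weights excluding the current class.  Defaults correspond to
  canonical resting values (≈ 3/s occurrence, ≈ 25 % coverage per class).
* **Between-subject dispersion** — a per-subject, per-class lognormal
  factor on mean duration with CV 0.15 (mid-range of cohort dispersions
  reported for these parameters).  Without it a group effect size on
  realized statistics would shrink with recording length and be an
  artifact of the chosen duration.
* **Rendering** — maps radiate a 10 Hz carrier with an Ornstein–Uhlenbeck
  log-envelope (τ = 0.5 s), one random polarity per sojourn (exercising
  polarity invariance), plus spatially white 1/f-shaped noise scaled to a
  target state-signal/noise RMS ratio (default snr 4); everything is
  average-referenced.  The rendered spectrum is alpha-dominant, as the
  preprocessing QC requires.
* **Group effects** — multiplicative perturbations of per-class duration
  and occurrence weight.  Because coverage is compositional, shrinking
  class D redistributes time to A/B/C; when an experiment requires class-C
  marginals to stay exactly fixed while D durations scale by s, the
  compensating entry weight w_D = 2/(3s−1) achieves this (derived from the
  stationary entry distribution of the exclusion chain).
* **Not modelled** — artifacts (blinks, muscle), volume conduction,
  non-alpha vigilance states, channel-specific noise spectra.  Passing
  recovery tests therefore demonstrates algorithmic correctness under the
  stated generative assumptions, not robustness to real-world artifacts.

Recordings are written as minimal continuous EDF+ (16-bit, 1-s records,
annotations channel) in a BIDS-like tree with a participants table and a
ground-truth JSON sidecar; reading goes through MNE's EDF reader.

## Problem sizes and numerical choices

Recovery experiments use 10–50 subjects at 60 s × 256 Hz, which keeps the
full suite fast while giving ~750 GFP peaks/subject and ~190 class-D runs
per subject — enough for stable per-subject statistics.  Calibration runs
use 2000 posterior draws per fit; grid comparisons default to 10 000.
Within-run determinism flows from single integer seeds through
`SeedSequence` substreams keyed by (group, subject).

Known limitations: the end-to-end two-group experiment at an induced
d ≈ −0.8 with n = 25/group sits near the power boundary of the 0.95 ROPE
decision — the realized cohort effect varies with SD ≈ 0.3 around its
target, so roughly a fifth of repetitions land below the detection
threshold, and detection tallies across a handful of repetitions
fluctuate accordingly.  Similarly, the posterior mean of d inherits the
sampling variability of the sample effect size (SD ≈ 0.19 at n = 60), so
per-repetition recovery within ±0.35 happens with probability ≈ 0.93, not
certainty.  These are properties of the experimental design, not of the
estimators.
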