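# Methods

`cortemg` implements an encoding/decoding analysis of chronic motor-cortex
and hindlimb-EMG recordings collected while a subject walks bipedally on a
treadmill, before and after a lateral (right) thoracic spinal hemisection.
The package consists of a synthetic multi-session generator that emulates
the statistical structure of such recordings, and the analysis chain that
consumes them: preprocessing, neural features, the maximal information
coefficient (MIC) as the encoding statistic, a ridge decoder evaluated by
cross-validated VAF, and session-level recovery statistics.

## The encoding statistic: MIC

For a paired sample D = {(r_i, m_i)} of a neural response value r and a
muscle-activity value m,

    MIC(D)   = max_{r·m < B(n)} M(D)_{r,m},
    M_{r,m}  = I*(D, r, m) / log2 min(r, m),
    I*(r, m) = max_G I(D|G)   over all r-by-m grids G,

with I(D|G) the plug-in mutual information (bits) of the grid-induced
contingency table and B(n) = n^alpha (alpha = 0.6 by default, exposed).
B(n) is floored so that a 2x2 grid is always admissible, which makes the
statistic well defined from n = 4 upward. Cut points are placed midway
between adjacent distinct sorted values, so ties are handled and the
statistic is exactly invariant under strictly monotone transformations of
either variable. MIC lies in [0, 1], is symmetric, is 1 for a noiseless
functional relationship and 0 when one marginal is constant.

Two search modes are implemented:

* **exhaustive** — enumerate every placement of cut points on both axes.
  Exact but combinatorial; usable only for tiny n. It serves as the
  reference the fast path is validated against (the test suite checks
  equality on hundreds of random fixtures with n <= 20).
* **heuristic** — for each grid shape, fix one axis and optimise the other
  exactly by dynamic programming over clump boundaries. The MI of a fixed
  column partition decomposes additively over row parts, which admits an
  exact prefix DP; one DP sweep yields the optimum for *every* row count at
  once, so the whole characteristic matrix costs little more than its
  largest shape. For small samples (n <= 32) the fixed-axis placements are
  fully enumerated (making the search exhaustive there); for larger samples
  the fixed axis uses a mass equipartition, and clump counts are capped at
  c x (axis size), c = 15 by default. Both orientations are searched and
  the maximum taken, which also guarantees exact symmetry. The heuristic
  maximises over a subset of the grids the exhaustive mode covers, so it
  can never exceed it.

Within the pipeline, the MIC sample for a (unit, muscle) pair pools the
per-step time-normalised bins of one session: the unit's smoothed rate
against the muscle's binned envelope (a flag switches to raw square-rooted
counts). Pooled samples are subsampled evenly to at most `mic_max_n` points
(500 by default) to keep the grid search affordable; because B(n) grows
with n, this also standardises the resolution at which sessions are
compared. A trial bootstrap (30 steps drawn with replacement, 100
replicates by default) quantifies the sample-size sensitivity of the
statistic, which is biased for small n.

## The decoder

Spike trains are counted in 20 ms bins, square-root transformed (variance
stabilisation for Poisson-like counts), and convolved with a Gaussian
kernel of 50 ms SD (normalised, truncated at 4 SD, reflective edges).
The design matrix stacks p = 4 past bins, the concurrent bin and q = 5
future bins per unit — 200 ms of surrounding activity per predicted EMG
bin, one row per 20 ms hop. Rows whose window leaves the recording are
dropped. By default decoding uses per-channel multiunit rates (units
sharing a channel are summed); the encoding analysis uses sorted single
units.

The decoder is ridge regression, beta = (X'X + lambda I)^-1 X'y, with an
unpenalised intercept (EMG envelopes have a nonzero baseline; X and y are
centred and the intercept recovered from the means). lambda is not tuned by
search: it is the smallest value for which the penalised Gram's condition
number is at most kappa_max = 10^3,

    lambda = max(0, (s_max - kappa_max * s_min) / (kappa_max - 1)),

with s_max, s_min the extreme eigenvalues of X'X. Every fit re-verifies the
cap. Performance is the variance accounted for,

    VAF = 1 - sum(yhat_i - y_i)^2 / sum(y_i - ybar)^2,

evaluated by 5-fold blocked cross-validation: contiguous (unshuffled)
temporal blocks, lambda re-selected on each training split to avoid
leakage, per-muscle VAF reported as mean +/- s.e.m. (SD of the 5 fold
values / sqrt(5)). VAF is at most 1 and goes negative when the prediction
is worse than the target mean.

## Preprocessing

* **Spike events** (raw-trace mode): 500-7500 Hz band-pass (4th-order
  Butterworth, zero phase), threshold at -(4.5..6.5) x RMS, negative-going
  crossings with a 1 ms lockout.
* **Unit QC**: a unit is retained if strictly fewer than 3 % of its
  inter-spike intervals are shorter than the refractory window (1 ms by
  default, exposed). Trains with fewer than two spikes pass with fraction 0.
* **EMG envelope**: full-wave rectification, zero-phase 4th-order
  Butterworth low-pass at 10 Hz, clipped at zero.
* **Artifacts**: an interval is flagged when >= 90 % of units spike inside
  one 1 ms window (simultaneous threshold crossings) or when the 50 ms RMS
  amplitude of any EMG channel exceeds 8x a robust scale. The robust scale
  is the 95th percentile of the RMS series: locomotor EMG is bimodal
  (rest floor vs bursts), which defeats MAD- or trimmed-SD estimates,
  while a high quantile tracks the physiological ceiling and stays
  uncontaminated by rare (< 5 % duty) artifacts. Flagged windows are
  padded by 50 ms and merged. Cleaning drops spikes inside the intervals,
  interpolates EMG across them and removes intersecting steps, so
  re-detection on cleaned data flags nothing (idempotence).
* **Step normalisation**: each step's samples are resampled by linear
  interpolation onto a fixed number of equispaced points from step start to
  end (endpoints included), one row per step, so steps of different
  durations become comparable. The pipeline uses one bin per nominal 20 ms
  of the step cycle (50 bins at 1 Hz stepping); standalone use defaults to
  100 bins. All bins and steps are half-open [start, end).
* **Locomotor ability**: steps per run of consecutive walking, their mean
  (the ability score), SD over runs (0 for a single run) and session total.

## Recovery statistics

Per session, MIC is summarised as mean +/- SD over the unit population per
muscle, and decoding as the cross-validated VAF mean +/- s.e.m. The drop at
the lesion is tested with Kruskal-Wallis (tie-corrected, chi-squared p);
both groupings are emitted — all sessions, and pooled pre-lesion versus the
first post-lesion session — because either comparison is scientifically
meaningful. The recovery trend is the Spearman rank correlation of the
per-session summaries against day index over post-lesion sessions only,
two-sided p. MIC values from different units are treated as exchangeable
observations within a session; their mutual dependence (shared gait drive)
is ignored, a known limitation shared with pooled per-unit dot plots.

## The synthetic generator

The generator emulates a macaque-scale chronic study: 13 weekly sessions (3 before
the hemisection; the first post-lesion session three weeks after surgery),
~1 Hz stepping at treadmill speeds 0.30-0.55 m/s, 64 initial units with a
~5 %/session decline (round-to-nearest geometric recursion), and six
muscles (LS, RS, LRF, RRF, RTA, LST; right side ipsilesional for a right
hemisection recorded from left motor cortex).

* **Units** fire as inhomogeneous Poisson processes with rate
  b + a·max(0, cos(2π·phase − φ)) during walking and b at rest; b ~ U(2,10)
  Hz, a ~ U(20,60) Hz, φ ~ U(0,2π), drawn once per study. A 1.5 ms
  absolute refractory period is enforced (without it, Poisson trains at
  locomotor rates violate any ISI criterion).
* **EMG** is the envelope itself plus rectified additive Gaussian noise
  (noise_sd = 0.1): a raised-cosine burst per cycle at a muscle-specific
  phase (width 0.35 cycle), multiplied by a drive equal to the
  coupling-weighted, normalised sum of the population's smoothed rates.
* **Lesion**: at the lesion session every coupling column is multiplied by
  its side's attenuation (ipsilesional 0.10, contralesional 0.60 — the
  ipsilesional deficit is constrained to be at least as severe), then
  relaxes exponentially toward baseline, g_k = 1 − (1−a)(1−ρ)^k with
  ρ = 0.15/session, leaving recovery visibly incomplete after ten
  post-lesion sessions, as in chronic hemisection data. The coupling
  deficit also disorganises the muscles directly: per-step burst-timing
  jitter (SD 0.18 cycle at full deficit) and log-normal per-step amplitude
  jitter (SD 0.6 at full deficit) shrink in proportion to (1 − g). Pure
  amplitude attenuation would be nearly invisible to scale-invariant
  statistics; the timing disorganisation is what makes early post-lesion
  ipsilesional EMG genuinely unpredictable (negative held-out VAF), as
  observed after real lesions (dragging, mistimed activation).
* **Behaviour**: walking comes in runs (Poisson-distributed lengths) with
  rest gaps. Pre-lesion runs average 85 steps with ~80 % of the session
  spent walking; immediately post-lesion runs shrink to ~15 steps and ~6 %
  walking, recovering toward 50 steps and ~65 % with g. Step durations
  jitter by 5 % (clipped at +/-30 %).
* **Artifacts**: broadband events at 3.5/min, 0.3 s long — simultaneous
  large deflections on all EMG channels plus coincident threshold events
  on every unit. With the detector's window and padding this removes ~3 %
  of the recording.
* **Determinism**: every random draw flows from
  `default_rng([seed, stream])` with fixed stream ids (study-level roster
  and coupling; one stream per session), so identical configurations
  reproduce byte-identical studies.

What the generator does **not** emulate: electrode drift within a session,
correlated (non-Poisson) spiking, EMG cross-talk, kinematics, and any
direct spinal (reflex/CPG) contribution to EMG that bypasses cortex — in
the model, everything predictable about EMG is cortical in origin. Passing
tests therefore demonstrate correctness and sensitivity of the analysis
chain under the stated statistical structure, not performance on real
recordings.

## Problem sizes

Analyses of the full default study (13 sessions x 600 s x 64 units) are
desk-scale but slow; the shipped tests and the acceptance script use
reduced study shapes chosen to preserve the phenomenology: 13 sessions of
150 s with 12 units (no dropout) for the recovery time course, 90 s with
32 dense-firing units for noiseless parameter recovery, 40-60 s sessions
with 2-6 units for null checks, and MIC subsampling caps of 100-400 points.
The parameter-recovery configuration uses a dense-firing population
(modulation 100-200 Hz) because its premise is the noise-free limit, and
spike-count noise is the dominant noise source in the decoder's input.
The type-I control of the trend test runs 200 independent studies with
recovery_rate = 0.

## Numerical choices

* Logarithms base 2 throughout MIC; the statistic is base-invariant
  because numerator and denominator share the base.
* Gaussian smoothing kernel truncated at 4 SD, reflective padding,
  renormalised to unit sum (constants are preserved exactly).
* Half-open binning everywhere; a spike exactly on an edge counts in the
  later bin; a spike exactly at the analysis end is excluded.
* Spearman/Kruskal-Wallis use midrank ties via scipy; a Kruskal-Wallis on
  groups whose pooled values are all identical returns (H = 0, p = 1)
  instead of scipy's error, matching the no-evidence reading.
* Degenerate inputs raise typed errors (constant targets in VAF, constant
  variables in Spearman, all-zero designs in lambda selection, < 4 points
  for MIC).
* The "80 % overlap" reading of 200 ms windows is not used: with a 20 ms
  hop, consecutive 200 ms windows overlap by 90 %, and the design matrix
  indexing (one row per bin) is taken as normative.
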