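# Methods

## Covering-design search

**Model.** Given a library of N compounds and a pool size n, a screen
design is a multiset of n-compound wells such that every one of the
C(N, 2) unordered compound pairs appears in at least one well. The well
count m is bounded below by ⌈C(N,2)/C(n,2)⌉; exact minimum covers
(covering numbers C(N, n, 2)) are only computable for tiny N, so the
search is heuristic and accepts near-optimal designs.

**Search.** Each pair carries a penalty, initialised i.i.d. U(0, 1), and
an active list holds the uncovered pairs. Per well, `trials` candidates
are generated: a candidate is seeded with one uniformly drawn active
pair and grown to n members by penalty-greedy completion — repeatedly
adding the compound whose pairs with the current members have the
smallest summed penalty. The candidate with the lowest total pair
penalty is accepted (ties: earliest sampled); its pairs are removed from
the active list and their penalties incremented by 1.0, which makes
re-use of a covered pair more expensive than any fresh pair and steers
subsequent wells toward uncovered territory. A run terminates when the
active list is empty; the search restarts from fresh penalties
`restarts` times and keeps the run with the fewest wells (ties: lower
redundancy, then earlier restart).

Greedy completion rather than uniform completion of candidates is a
deliberate choice: each candidate is then a local minimum of the penalty
score given its seed pair, and the achieved well counts drop from ~176
to ~125–135 for N = 80, n = 10 while the search gets ~20× faster.
Diversity across candidates comes from the random seed pairs; diversity
across restarts from the random initial penalties.

**Defaults and units.** `restarts = 50`, `trials = 1000`,
penalty increment 1.0, initial penalties U(0, 1). All are dimensionless.
Seeding is hierarchical: restart r uses child r of
`numpy.random.SeedSequence(seed)`, so designs are bit-reproducible and
restarts are independent streams. Compound-usage balance is reported by
`verify_coverage` but not constrained.

**Degenerate cases.** n = 2 forces m = C(N, 2) (each well is one pair);
n = N forces m = 1. Both fall out of the search without special casing.
For all N ≤ 6 and every valid n, 30 restarts reproduce the exact optimum
found by an independent branch-and-bound over candidate wells (see
`tests/oracles.py`).

**Calibration.** `calibrate` maps median m over a grid of (N, n) using
five iterations per cell by default, each with a seed derived from a
stable (cell, iteration) spawn key so inserting or skipping cells does
not shift other cells' seeds. The reported rate series is the change in
median m per step in n at fixed N. Calibration defaults to lighter
search settings (`restarts = 10`, `trials = 500`) than a production
design because the grid multiplies runtime; the qualitative shape
(m non-increasing in n, increasing in N) is insensitive to this.

## Screen analysis

**Normalization.** Readings are divided by the mean (configurable:
median) of the vehicle-control wells of their (plate, cell line, time
point) stratum. A stratum without a positive vehicle level is an error,
not a silent pass-through. Normalization is idempotent on an
already-normalized screen and hit calls are invariant to rescaling raw
RFU within a stratum (units cancel).

**Hit rules.** Single agents: hit ⇔ normalized RFU ≥ 2 (inclusive), the
conventional "cell death occurred" call for a cytotoxicity readout.
Combination wells: hit ⇔ value > mean + 3·SD, with mean and SD taken
over all combination wells of the cell line at the decision time point
(default 72 h), excluding vehicle and cytotoxic-control wells; the SD
uses ddof = 1. The two rules deliberately differ in strictness of the
boundary (≥ vs >), matching their conventional definitions. Note the
3SD rule is self-referential: planted effects inflate the SD, so it
needs a realistically large background population (dozens of wells) to
behave well — one reason the bundled scenarios are screen-scale.

**Attribution.** For a hit pool, effects are compared on the excess
scale e(x) = max(x − 1, 0). With α = 0.8 and τ = 0.2 (both
configurable): single-agent-driven if one member's excess ≥ α × pool
excess; else additive if the summed member excesses ≥ pool excess − τ;
else candidate-synergy. The excess scale makes the simulator's additive
composition exactly recoverable at zero noise; α and τ absorb assay
noise in real data. The classification is a total, deterministic
function of its inputs for fixed tolerances.

**Deconvolution.** A hit pool of k compounds expands to its k(k−1)/2
pairwise wells at a single dose (default 0.1 µM, carried over from the
pooled screen), in canonical library order.

## Synergy

Single-agent curves are fitted by ordinary least squares on the
median-effect linearisation log(fa/(1−fa)) vs log D; fa values are
clipped into [1e−3, 1−1e−3] to keep the logit finite (configurable).
Measured fa is most informative roughly within 0.1–0.9; dose designs
should bracket the IC50 inside that band, since fa noise is amplified by
the logit outside it. The combination index uses the mutually exclusive
form CI = d1/Dx1 + d2/Dx2 with Dx_i = Dm_i (fa/(1−fa))^(1/m_i).
Because measured CIs never equal 1 exactly, classification uses an
additive band δ = 0.05: synergistic below 1 − δ, antagonistic above
1 + δ. Cells of a dose matrix outside either compound's fitted dose
range are scored but flagged as extrapolations. For a cytotoxicity
readout, fa is obtained from normalized RFU by anchoring the vehicle
level at 0 and a maximal-kill level (cytotoxic-control well) at 1 and
mapping linearly.

Sham self-combinations (one drug split across both "positions")
evaluate to CI = 1 up to 1e−9 for any split fraction — the analytic
identity used as the primary correctness check of the CI code.

## Simulator

**Generative model.** A well's expected vehicle-normalized value is
1 + Σ single-agent excesses of its members + Σ synergy boosts of planted
pairs fully contained in the well; observed raw RFU is
baseline × expected × exp(N(0, noise_sd)). Additive composition on the
excess scale mirrors the attribution rule, so at zero noise every
pipeline stage inverts the simulator exactly; multiplicative log-normal
noise is the conventional model for plate-reader variability. Defaults:
baseline 1000 RFU, noise_sd 0.1, six vehicle wells per stratum, one
cytotoxic-control well per plate at normalized 7.0 (high-signal,
MV4-11-like lines) or 1.5 (low-signal, CMK-like lines). Planted toxic
singles act at every tested concentration; within-screen dose-response
and kill kinetics over time are deliberately not modelled (dose matrices
cover the dose dimension separately).

**What passing tests show.** The simulator reproduces the *structure* of
a pooled cytotoxicity screen — strata, controls, effect composition,
noise scale — not its biology: no growth kinetics, spatial plate
effects, compound interactions beyond planted pairs, or heavy-tailed
outliers. Recovery results on simulated screens therefore validate the
pipeline's logic and statistics, not its performance on any particular
real cell line.

**Scenarios.** `null` (no effects), `singles_only` (five toxins at
multiplier 3.0 among 80 compounds), `additive_only` (six moderate toxins
at 1.8), `well155_like` (ten named near-inert compounds — the planted
synergistic pair is ABT-737 + Purvalanol A at boost 2.5 in the
MV4-11-like line, with a weak second pair in the CMK-like line —
embedded in an otherwise inert 80-compound library so the 3SD rule has a
realistic background), and `flt3itd_mllr` (the identified pair against a
seven-line panel with the boost present in exactly the two lines
carrying both lesions). Effect magnitudes are chosen so planted effects
sit well clear of the hit thresholds at the default noise (boost 2.5 →
pool value ≈ 3.5 against a background SD of ~0.1) while faint
single-agent activity (≤ 1.15) stays below the 2× line. Dose-matrix data
are generated by choosing, per dose pair, the combined fa whose CI
equals a target value exactly (bisection on the strictly decreasing
CI(fa)), giving a round-trip oracle for CI estimation.

**Checkerboard/problem sizes.** The bundled tests run the full
80-compound, 10-per-well configuration (50 restarts) once, 100-replicate
deconvolution recovery, 20-replicate end-to-end recovery, and 5-iteration
calibration at N = 40 — about half a minute in total, chosen to keep the
suite convenient for routine development runs.

## Known limitations

- The covering search optimises well count only; it does not balance
  per-compound usage, respect plate/batch boundaries, or support t-wise
  coverage beyond pairs.
- The 3SD combination rule assumes hits are rare; screens where a large
  fraction of wells respond will mask true hits by inflating the SD.
- Attribution thresholds (α, τ) are heuristics for a noisy excess scale,
  not calibrated error rates.
- CI classification inherits the median-effect model's assumptions
  (log-linear dose-response, mutually exclusive action); dose matrices
  from drugs with non-sigmoidal responses will mis-fit upstream of CI.
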