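# Methods

This note defines the statistical model and procedures implemented in
`fourc`, records the default parameters and the reasoning behind the
numerical choices, describes what the synthetic-data generator does and does
not cover, and lists known limitations.

## 1. Reduced genome and fragment counts

A 4C read maps immediately adjacent to a restriction site, so only the
`read_len` base pairs flanking each site are informative.  `fragmap` digests
the genome with the enzyme motif (e.g. `GATC`) and emits, per site, the
upstream and downstream flanks of length `read_len`, truncated at chromosome
edges.  A flank whose sequence occurs more than once in the reduced genome is
flagged non-unique and never receives counts.  Reads are assigned to flanks by
exact position; a *fragment* here means one flank, and a fragment is
*observed* in a sample when its count is ≥ 1.

**Bait masking.**  Self-ligation and re-ligation inflate counts at and
immediately around the bait.  The bait fragment and the `bait_radius` flanks
on each side (default 2) are zeroed before any downstream step.

**Quality control** per sample: ≥ 1 M mapped reads, ≥ 40 % of reads on the
bait chromosome, and ≥ 40 % of fragments observed within the near-bait span
(2 Mb around the bait for 6 bp cutters, 200 kb for 4 bp cutters).  These are
screening thresholds for real libraries; the CLI warns by default and only
`--strict` makes failure fatal, because desk-scale simulations legitimately
fail the depth threshold.

## 2. Adaptive windows

Fragment density varies along the genome, and windows should hold a roughly
constant amount of information rather than a constant number of base pairs.

* **k-NN sizes.**  For each observed fragment position, the window size is
  the distance to its k-th nearest *downstream* observed fragment; near the
  chromosome end, where fewer than k downstream fragments remain, the k-th
  upstream distance is used instead.  Sizes are floored at 1 bp.
* **Smoothing.**  The (position, size) pairs are fitted with a smoothing
  spline whose penalty is chosen by generalized cross-validation.  To keep
  the fit cheap and balanced, at most 1000 anchor points are used, chosen so
  each anchor represents an equal share of the observed fragments.  With
  fewer than 5 distinct anchors (the minimum the spline fitter accepts) the
  profile falls back to linear interpolation with a warning.
* **Chaining.**  Windows overlap by half: the next window starts at the
  integer midpoint `(start + end) // 2` of its predecessor.  On cis
  chromosomes two chains grow outward from the bait (the left chain mirrored,
  with strictly decreasing window ends); trans chromosomes get a single
  left-to-right chain.  The terminal window of a chain is truncated at the
  span boundary.  Per-sample size profiles are pooled and refitted so that
  all replicates share one window set.
* **Defaults for k**: near-bait 5, whole-chromosome cis 10, trans 15 for
  6 bp cutters and 100 for 4 bp cutters (trans coverage is far sparser, and
  4 bp cutters produce many more fragments per window span).

## 3. Normalization and observations

Within each window and sample, fragment counts are summed after trimming:
each fragment's count is capped at the window's 75th percentile
(quantile type 7) computed over the window's *observed* fragments.  This
suppresses single-fragment spikes (e.g. PCR artifacts) without discarding the
window.  Note the cap itself changes when counts change, so re-trimming an
already-trimmed window can shrink it further; trimming is monotone
(never increases a window's total) but not idempotent.

Size factors across samples are median-of-ratios: the median over windows of
each sample's ratio to the per-window geometric mean, computed on windows
with all-positive counts, on the ratio scale.

The HMM observations per window are `x = log10(normalized count + 1)` for
each replicate and, on cis chromosomes, the covariate
`z = log10(distance of window midpoint to bait + 1)`.

## 4. Constrained three-state Gaussian HMM

States are NI = 1, LI = 2, HI = 3.  Parameters are the initial distribution
π (3), the transition matrix A (9), and the emissions:

* **cis**: state means are linear in the distance covariate,
  `μ_i(z) = β0_i + β1_i z`, with constraints `β0_1 + ε ≤ β0_2 ≤ β0_3 − ε`
  (ε_β = 0.1) and `β1_i < 0` (signal decays with distance); 3 intercepts +
  3 slopes + 3 standard deviations → **21 parameters** total.
* **trans**: constant means `μ_1 + ε ≤ μ_2 ≤ μ_3 − ε` (ε_μ = 0.05);
  **18 parameters** total.

Standard deviations are floored at 0.05 to keep the likelihood bounded
(without a floor, a state can collapse onto a single observation and drive
the likelihood to infinity).

**Fitting** is direct maximum likelihood: parameters are mapped to an
unconstrained vector (softmax for π and rows of A; lowest mean plus
`ε + exp(gap)` increments for the ordered means; `−exp` for the negative
slopes; `floor + exp` for the standard deviations) and optimized with
L-BFGS-B on the forward-algorithm log-likelihood.  The forward pass and
Viterbi decoding are numba-compiled, scaled, linear-space recursions; on
Viterbi ties the lower-numbered state wins, a deterministic and conservative
choice (prefers the less-interacting label).  Replicates are emission
columns sharing one state path during fitting, and are decoded separately
afterwards.

**Initialization**: π uniform; A 0.5 on the diagonal, 0.25 off; observations
are split into 30-window segments and classified by the segment's 60th/90th
quantiles; the HI regression is fitted on the top class, then
`β0_2 = 0.8 β0_3` and `β0_1 = 0.5 β0_3` (gap-repaired to respect ε if
needed).

**Bootstrap training.**  To avoid overfitting any one replicate, the model
is trained on a composite sequence: window breakpoints are placed at every
2nd window; within each block on cis chromosomes (and per chromosome on
trans) the emission column of one replicate, chosen uniformly at random, is
used.  Training requires ≥ 2 replicates.

**Domain calling.**  Per replicate, maximal runs of HI windows become
domains; a run is trimmed where its boundary windows abut non-HI
neighbours within the same side chain (overlapping windows otherwise smear
domain edges by half a window).  The consensus is the base-pair intersection
of the replicate domain sets.

## 5. Replicate similarity, differential testing, enrichment

* **Similarity.**  Domains are first filtered: a domain is retained only if
  ≥ 50 % of its length is covered by the union of the other replicates'
  domains.  With a_S the base pairs in the intersection of subset S of the
  retained sets and U their union, the score is
  `CS_m = m/(m−1) · (Σ_{|S|=2} a_S − Σ_{|S|=3} a_S + …) / U`,
  which equals m for identical sets and 0 for disjoint ones; dividing by m
  gives a [0, 1] value comparable across replicate counts.
* **DIDs.**  The testing universe for two conditions is the union-merge of
  their consensus domains, with per-interval provenance labels.
* **Differential test.**  Window counts inside DIDs are size-factor
  normalized; per-window NB dispersion is estimated by method of moments
  pooled across conditions, then floored at the across-window mean estimate
  (with 2–3 replicates a per-window moment estimate is far too noisy; this
  floor is a crude but effective form of dispersion sharing).  A Wald test
  on the log mean ratio with delta-method variance `(1/μ + α)/n` per
  condition gives p-values, adjusted by Benjamini–Hochberg.
* **Peak enrichment.**  The observed peak base pairs inside domains are
  compared with a null in which all domains are repositioned uniformly at
  random, size-preserving and non-overlapping (rejection sampling, 1000
  tries per domain), R = 1000 times.  The statistic is
  observed / mean(null).

## 6. Synthetic-data generator

`synthbench` simulates a uniform-random genome (default one 2 Mb
chromosome), digests it, and draws per-fragment counts from a negative
binomial whose log-scale mean follows the cis HMM emission model: background
decay `β0_1 + β1 log10(d+1)` with `β0 = (0.9, 1.45, 2.1)`, `β1 = −0.14`,
Gaussian log-scale noise σ = 0.22, NB dispersion 0.05, two replicates, truth
consisting of two HI and two LI domains.  Non-unique fragments get zero
counts; optional spikes multiply a random fragment subset.  Truth domains
are written as BED, and `end_to_end_recovery` runs the full pipeline
(fragmap → windows → normalize → HMM → consensus) and scores base-pair
precision and recall against the truth plus the replicate similarity.

The generator deliberately covers only the dominant axes of difficulty:
distance decay, irregular fragment spacing, overdispersion, mappability
holes and count spikes.  It does **not** model ligation-junction chemistry,
mapping error, GC bias, copy-number variation, trans contacts between
simulated chromosomes, or undigested-fragment carryover.

## 7. Numerical choices (summary)

| choice | value | why |
|---|---|---|
| σ floor | 0.05 | bounded likelihood; prevents state collapse |
| ordering slack ε_β / ε_μ | 0.1 / 0.05 | identifiable, strictly separated states |
| k-NN direction | downstream, mirrored at end | one-sided sizes keep windows anchored at their start |
| spline anchors | ≤ 1000, count-balanced; ≥ 5 or linear fallback | cost control; fitter minimum |
| size-factor median | ratio scale | matches the estimator's definition; robust to even window counts |
| dispersion floor | across-window mean | moment estimates from 2–3 replicates are unusably noisy alone |
| Viterbi tie-break | lower state | deterministic, conservative |
| bootstrap blocks | every 2nd window | mixes replicates at sub-domain scale |
| optimizer | L-BFGS-B on reparameterized ML | honors constraints exactly, no projection steps |

## 8. Limitations

* **Forced state-splitting.**  The model always has three states.  When the
  data contain fewer than three populations (e.g. no true HI domains), the
  strongest remaining population is inevitably labelled HI.  Calls in that
  regime concentrate on the highest-signal regions rather than disappearing;
  interpret HI calls relative to the dataset, not as an absolute category.
* **HI/LI merging.**  At low depth the likelihood can have local optima in
  which HI and LI merge into one broad elevated state (large σ, near-zero
  slope); the consensus then covers elevated regions without distinguishing
  their strength.  Multi-seed benchmarks show this is seed-dependent, not
  systematic.
* **Consensus granularity.**  Base-pair intersection of per-replicate calls
  fragments domains at window boundaries; at low coverage a single true
  domain is typically recovered as several abutting intervals.
* **Differential test calibration** relies on the dispersion floor; with
  many replicates the floor becomes conservative, and with a single
  replicate per condition (allowed only by explicit override) the test has
  no dispersion information at all.
* The trimming cap is not idempotent (section 3); quoted trimmed counts are
  defined by exactly one trimming pass over raw counts.
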