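# Methods

`pparscreen` re-implements, at a testable scale, the analysis chain of a
loss-of-function screen in *Xenopus laevis*: control ("Co") versus PPARβ
morpholino ("MO") embryos are compared by tag-based RNA counting, candidate
PPARβ-promoted genes are screened by ChIP-qPCR for the repressive H3K27me3
mark, and the association between the mark and PPARβ-dependent promotion is
tested exactly. Every stage can be driven by a synthetic-data generator
that injects known ground truth, so recovery is measurable end to end.

## Paired-end tag mapping

Tags are mapped ungapped onto a transcript set. A pair is admitted when its
two mates carry at most 5 `N` characters in total; each mate may align with
at most one mismatch; `N` in a tag is a wildcard that matches any base at
zero mismatch cost (the only reading under which the two filters are
mutually consistent). A valid hit requires both mates on the same mRNA in
convergent (FR) orientation — the paired-end standard; either mate may be
the forward one — with an outermost span (rightmost end − leftmost start,
0-based half-open coordinates) of at most 500 nt, on exactly one mRNA.
Pairs placing on two or more mRNAs are rejected as ambiguous; several
placements on a single mRNA are resolved by fewest total mismatches, then
leftmost coordinates. Rejection reasons (`n_filter`, `no_hit`, `too_far`,
`multi_mrna`) are exhaustive and mutually exclusive. Each valid pair counts
once toward its mRNA's abundance. The matcher is verified against a
brute-force all-offset scan; no indexing is attempted because the package
targets fixture-sized transcript sets, not the multi-million-tag scale of a
production aligner.

## Count normalization and ranking

Under the assumption that the knock-down leaves most genes unaffected, the
MO column is multiplied by the ratio of the Co and MO medians, computed
over genes detected in at least one condition. Because the median is
positively homogeneous, this equalizes the two medians exactly; the
five-number summaries (lowest, quartiles, maximum; linear-interpolation
quantiles) are reported on the same detected subset. The originally
published factor (0.799) can be supplied as an override. Per-gene fold is
`(adjusted MO + c) / (Co + c)` with pseudocount `c = 0.5` (guards zeros;
the source analysis does not state its zero handling). Rank 1 is the most
downregulated gene — the strongest candidate for a PPARβ-promoted
transcript; ties break by higher Co count, then gene id. The promoted
candidate set is the top 200 by this rank; control candidates are genes
with fold in [0.9, 1.1] (the "no change" band is not quantified in the
source; both bounds are configuration fields).

Measured behaviour worth knowing: with the default count model (below),
recovery of injected 4× knockdowns into the top-200 set plateaus around
0.85 — the limit is the null fold spread at per-library CV ≈ 0.32, not the
ranking rule. The scale-factor estimate itself is within 10% of the
injected truth at n = 2000.

## qPCR quantification

**Ct calling.** Baseline = mean of the first three cycles (simplest
defensible choice, recorded in configuration). Ct is the fractional cycle
at which the corrected fluorescence first crosses the threshold,
interpolated in log space (exact while growth is exponential). A curve
that never crosses is flagged as no-amplification.

**Efficiency estimation (window of linearity).** For each well of a
primer, regardless of condition, the best log-linear window of `window`
(default 5) consecutive cycles is found by maximizing R²; the well's
efficiency is `10**slope` and the primer efficiency is the mean over wells
with R² ≥ `min_r2` (default 0.99). Late-cycle fluorescence saturates, and
a raw log-linear fit is biased low wherever the window approaches the
plateau (the instantaneous log-slope is `log E · (1 − F/Fmax)`). When a
curve has demonstrably plateaued (last three cycles flat within 5% of the
peak), the corrected signal is therefore linearized as `y / (1 − y/peak)`
before the window fit, which removes the bias for logistic-type
saturation; curves that never plateau are fitted on the raw log scale.
Candidate windows are restricted to 2–80% of the peak to stay clear of the
noise floor and the plateau. Monte-Carlo recovery under the generator:
maximum error 1e-4 noise-free and < 0.03 at noise 0.005·Fmax (8 wells).

**Relative quantities.** `RQ = E**(Ct_cal − Ct)` with the per-gene mean Ct
across samples as calibrator (the single-gene-efficiency convention of
standard qPCR software; the calibrator choice is a convention, not a
result). Per sample, quantities are divided by the geometric mean of the
reference genes (EEF1a and RPL8 by default); the operation is idempotent.
MO/Co folds are computed per replicate and reported as mean ± S.E.M.
across biological replicates (S.E.M. undefined with a single replicate).

## ChIP-qPCR scoring

Percent input is `E**(Ct_input − Ct_sample) × 100`; no dilution-correction
term is added, so input Cts are assumed pre-adjusted. Enrichment is the
IP's percent input over the negative control's (empty beads for the
histone marks; the PPARβ-MO signal for the PPARβ antibody). A locus is
positive for a mark iff **both** strict inequalities hold: percent input
> 1% and enrichment > 5. Boundary cases (exactly 1%, exactly 5×) are
negative. A gene positive for H3K4me3 and H3K27me3 is bivalent. The
screen scorer tabulates positives in the promoted and control sets for
the contingency test.

## Developmental dynamics

For each consecutive stage pair, genes whose level changes by at least 2×,
4× or 8× (inclusive thresholds; "by t×" is read as at-least) in either
direction are counted and divided by the transition's duration in hours.
Both levels are floored at half the smallest positive observed level
before the ratio, making increase/decrease symmetric and zero-safe; counts
are nested by construction (8× ⊆ 4× ⊆ 2×). The burst set holds genes
induced ≥ 4× over the designated gastrula transition (stage 11 → 13), and
its persistence is summarized by per-stage 10/25/50/75/90th percentile
envelopes.

## Epigenetic classification and enrichment test

A gene is 'K27' when its ortholog carries H3K27me3 regardless of H3K4me3
co-occupancy, 'K4_only' when only H3K4me3 is present, 'unmarked' when
neither; genes absent from the state table are 'unclassified' and excluded
from contingency building (only measured genes were screened). The class
is conserved when mouse ESC and zebrafish-blastula states agree on K27 or
K4_only; with one species, its class is retained unconserved; on
disagreement the K27 call dominates as the deterministic primary class.

The Fisher exact test is implemented from log-gamma hypergeometric point
probabilities. The two-sided p sums all tables with the observed margins
whose point probability is at most the observed one (1e-12 relative
tolerance against ties lost to floating point); the one-sided p is the
upper tail; the odds ratio is the sample `ad/bc` (infinite when `bc = 0`).
Sidedness is reported both ways since the source does not state it; the
screen table (14/21 vs 1/26) rejects at 0.005 either way. The
implementation is tested exhaustively against a rational-arithmetic
enumeration for all tables with total ≤ 18 and against an independent
library implementation on random tables.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions and are not tuned per experiment.

- **Counts.** Per-gene Co means are log-normal with median ≈ 99 counts and
  sd(log) = 1.8, calibrated so the quartiles of a 2 000-gene draw resemble
  the published five-number summaries (26 / 99 / 305). Counts are
  negative-binomial (Gamma–Poisson), dispersion 0.1 (variance
  `m + 0.1 m²`); the source is silent on count noise, and dispersion is a
  configuration field. MO means are Co means × injected per-gene fold
  (default: 100 genes down, 50 up, folds 2–8×) × a global library scale
  (default 0.8, the ground truth for normalization).
- **Tags.** Pairs are extracted from transcripts in convergent orientation
  with span ≤ 500 nt, then corrupted by per-base substitution and
  N-masking; pairs that exceed the admission filters are pre-flagged, and
  decoys are random sequences. Provenance (source transcript, positions)
  is recorded for recall measurement.
- **qPCR curves.** Fluorescence is baseline + `u/(1 + u/Fmax)` with
  `u = F0 · E^cycle` plus Gaussian noise (default sd 0.5% of Fmax); true
  efficiency, F0 and the exact threshold-crossing cycle are recorded per
  well, so any estimator can be validated against them. MO wells can start
  from a fold-scaled template to inject a knockdown.
- **ChIP Cts.** Sample Cts are generated by exactly inverting the
  percent-input formula, so the formula is recoverable by construction
  (e.g. E = 2, 25% input ⇒ sample trails input by exactly 2 cycles).
- **Time course.** Stages are a consecutive subset of Nieuwkoop–Faber
  stages with one designated gastrula transition standing in for
  stage 11 → 13. Baseline genes drift slowly in log space; burst genes
  jump ≥ `burst_fold` (default 8) at that transition and never fall below
  50% of their induced level afterwards.
- **Ortholog states.** Promoted and control genes (35/27 by default, the
  screen's sizes) carry K27 with probabilities set so the expected odds
  ratio equals `k27_odds_ratio` (default 17.3, the screen table's sample
  odds ratio) over a baseline of 1/27. The second species copies the first
  with probability `conservation_prob` (default 0.8).

What the generator does **not** emulate: read-level sequencing error and
base qualities, genome-scale transcriptomes, inter-plate qPCR calibration,
antibody efficiency and chromatin-fragment effects in ChIP, and the
microarray normalization behind the real developmental time course.
Passing recovery tests therefore demonstrates the correctness and internal
consistency of the computations, not robustness to every artefact of real
data.

## Problem sizes

Tests and the acceptance script run the count model at 2 000 genes,
mapping fixtures at tens of transcripts, qPCR at 8 wells per primer, the
enrichment screen at the study's own 35 + 27 genes (200 replicate
simulations), and the time course at 500–1 000 genes — sizes chosen so the
statistical claims are testable while the whole suite stays fast.

## Known limitations

- The mapper is a reference implementation (O(transcripts × offsets) per
  tag); it is not meant for genome-scale libraries.
- The normalization factor is a median ratio; the source's exact statistic
  behind its published 0.799 is unknown, so that value is reproducible
  only via the override.
- S.E.M. of qPCR folds is computed across biological replicates only; no
  error propagation from the efficiency estimate is attempted.
- The Fig-3-style per-transition counts depend on the third-party
  time-course data and are validated here only property-wise (nesting,
  scale invariance, burst recall) on synthetic courses.
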