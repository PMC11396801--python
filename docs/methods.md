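# Methods

## Data model

A biological sample is keyed by (treatment, timepoint in hours, replicate
index); a `CtTable` is the gene × sample grid of raw cycle-threshold values.
Non-missing Ct must lie in (0, 45] — values beyond a 45-cycle run are
physically implausible — and a separate plausibility screen lists values
outside a configurable band (default [10, 40], bracketing the 17–25 range
typical of moderately expressed transcripts).  Genes and samples are kept in
canonical sorted order so results never depend on input row order.

Biological replicates aggregate by the **arithmetic mean of Ct**.  Ct is
already a log₂-scale quantity (one cycle ≈ one doubling), so the arithmetic
mean of Ct is the geometric mean of linear abundance — the convention that
keeps downstream log-ratio statistics unbiased.  Replicate count and
SEM = SD/√n are carried per cell.  Missing replicates are tolerated; a
(gene, condition) cell with zero usable replicates becomes missing, and any
gene with a missing cell inside a requested treatment subset is dropped from
stability analysis for that subset with a warning (the algorithms require
complete grids).

## Efficiency calibration

A dilution series at base $b$ (default 5-fold) places level $i$ at relative
concentration $b^{-i}$.  Ordinary least squares of Ct on
$\log_{10}$(concentration) gives slope $k$ and intercept; replicate Ct at a
level enter as individual points rather than pre-averaged means, so $R^2$
reflects replicate scatter.  Efficiency is the standard conversion
$E = 10^{-1/k} - 1$, so $k = -3.3219$ ⇔ $E = 100\%$ (exact doubling).  $R^2$
is the squared Pearson correlation of the same fit, matching what
instrument software prints.  A non-negative slope leaves $E$ undefined
(NaN) and automatically fails QC.  Primer acceptance defaults:
$0.90 \le E \le 1.20$ (inclusive) and $R^2 \ge 0.99$.

## Stability statistics

All four methods consume the replicate-mean Ct frame of one treatment subset
and emit "lower = more stable" scores plus average-rank-on-ties rankings.

**Relative quantities.**  $Q_{g,s} = (1+E_g)^{\min_{s'} Ct_{g,s'} - Ct_{g,s}}$,
so each gene's most abundant sample has $Q = 1$.  The default $E = 1$
reproduces the classical $Q = 2^{-\Delta Ct}$.

**geNorm.**  For genes $j, k$: $V_{jk} = \mathrm{SD}_s[\log_2(Q_j/Q_k)]$
(sample SD, ddof 1) and $M_j = \mathrm{mean}_{k \ne j} V_{jk}$.  The gene
with the highest $M$ is removed and $M$ recomputed until two remain; a
gene's reported score is its $M$ at the round of removal (the stepwise
convention used in published stability charts; the first-round single-pass
$M$ is available via `GenormResult.rounds[0]`).  The surviving pair is
unresolvable by construction and shares average rank 1.5.  Tie removals are
broken by gene name so results are invariant to input permutation.  The
pairwise-variation curve uses normalization factors
$NF_n$ = geometric mean of $Q$ over the $n$ most stable genes:
$V_{n/n+1} = \mathrm{SD}_s[\log_2(NF_n / NF_{n+1})]$, and the recommended
set size is the smallest $n$ with $V$ **strictly** below the threshold
(default 0.15); if none qualifies, all genes are recommended with a warning.

**NormFinder-style score.**  Columns are first centered by their cross-gene
mean, removing sample-loading effects, giving residuals $w$.  Without
groups, the score is $\mathrm{SD}_s(w_g)$.  With groups (the treatment
labels when a subset pools several): per gene and group, the group mean
$m$, its deviation $z$ from the gene's across-group mean, and the
within-group variance $\sigma^2$; a common between-group variance
$\gamma^2 = \max(0, \mathrm{Var}(z) - \mathrm{mean}(\sigma^2/n))$ shrinks
the bias, $\tilde z = z\,\gamma^2/(\gamma^2 + \sigma^2/n)$, and the score is
the group-mean of $|\tilde z| + \sqrt{\sigma^2/n + \gamma^2 (\sigma^2/n) / (\gamma^2 + \sigma^2/n)}$.
The published tool leaves its small-sample constants unstated, so this
explicit empirical-Bayes variant is fixed here for reproducibility;
agreement with the original is expected at the rank level, not the third
decimal.  Groups of size 1 are rejected by name.

**BestKeeper.**  Per gene: mean Ct, sample SD (ddof 1) and CV% =
100·SD/mean.  SD strictly greater than 1 cycle flags the gene unstable;
flagged genes are still ranked (SD ascending, CV% tiebreak, gene name as
final deterministic tiebreak) so consensus aggregation stays total, and the
flag is carried through to the consensus output.  The original tool's
mean-absolute-deviation variant sits behind `use_mad=True`.  The BestKeeper
index is the per-sample geometric mean of the Ct of SD-surviving candidates;
each gene's Pearson r (and two-sided p) against the index is reported, and
the step is skipped with a warning when fewer than three candidates survive.

**Comparative ΔCt.**  Score = mean over partners of
$\mathrm{SD}_s(Ct_g - Ct_h)$.  On $E = 2$ data this equals geNorm's
single-pass $M$ exactly (log₂ ratios of $Q$ are negated Ct differences), a
cross-check asserted in the tests.

**Consensus.**  Equal-weight geometric mean of the four methods' ranks,
re-ranked with average ties.  (The published web aggregator's internal
weighting is unpublished; equal weights are the one documented
interpretation here.)  The best pair is the top two by final rank, name
order on exact ties.  Note one aggregation subtlety: adding a *duplicate* of
an existing method can legitimately reorder near-ties (it reweights the
geometric mean); only a method concordant with the consensus itself is
guaranteed order-preserving.

## Relative expression and validation

For target $t$ under references $R$: per replicate
$\Delta Ct = Ct_t - \mathrm{mean}_{r \in R}(Ct_r)$ — the arithmetic mean of
reference Ct equals the geometric mean of their linear quantities —
then $\Delta\Delta Ct = \Delta Ct - \overline{\Delta Ct}_{\mathrm{cal}}$
over the calibrator's replicates, and $RQ = 2^{-\Delta\Delta Ct}$.  The
calibrator defaults to the 0 h condition of each sample's own treatment
(within-treatment time courses); a fixed (treatment, timepoint) may be
pinned instead.  Because centering happens on the log scale, the *geometric*
mean RQ at the calibrator is exactly 1 (its arithmetic mean exceeds 1
slightly by Jensen's inequality — the usual convention).  An
efficiency-corrected ratio mode replaces base 2 with per-gene $(1+E)$ and
reduces exactly to $2^{-\Delta\Delta Ct}$ when all $E = 1$.

Timepoint significance uses a two-sided **Welch** t-test on log₂ RQ
(equivalently $-\Delta\Delta Ct$) versus the baseline timepoint: fold
changes are approximately log-normal, so the log scale is where a t-test is
defensible; Welch avoids the pooled-variance assumption.  Stars: ** for
p < 0.01, * for p < 0.05.  No multiple-testing correction is applied by
default (per-timepoint stars are the field's reporting convention); with
three replicates the test is mildly conservative (empirical size ≈ 3–4% at
nominal 5%), which the acceptance suite checks stays within the binomial
99% CI around 0.05.  Conditions with fewer than two replicates are flagged
undefined rather than tested.

Normalizer concordance compares profiles of one target under different
reference sets: Pearson correlation of log₂ mean fold changes over the
shared condition grid, fraction of treatments with matching peak timepoint,
and a flag below a configurable correlation threshold (default 0.9).

## Synthetic data generator

The generator emulates the study design the package targets: treatments
MeJA, EtH, SA on a 0/3/6/12/24/48 h grid and HighTem, LowTem on
0/6/12/24/36/48 h (the two grids are deliberately different), 3 biological
replicates, and

$Ct = \mathrm{baseline} + \mathrm{shift}(\mathrm{treatment}, t) + \mathrm{loading}_s + \mathcal N(0, \sigma_g^2)$.

The per-sample loading offset (default SD 0.3 cycles) models cDNA input
variation — exactly the common-mode nuisance normalization removes — and
cancels from every log-ratio statistic, which the tests assert.  Noise is
Gaussian on the Ct scale (instrument-like).  Baselines sit in the 17–25
band typical of such panels.

The study-like candidate panel fixes, once: two designed-stable genes
(SsCDC6, SsNCBP2; no treatment response, noise 0.67σ), one designed-unstable
gene (SsPP2A; linear drift of 2 cycles over 0–48 h in every treatment,
noise 2σ), and nine intermediates with constant treatment biases
(0.4–0.7 cycles), milder drifts, or inflated noise, with σ = 0.15 cycles by
default.  Fourteen pathway-target genes carry designed log₂ fold-change
trajectories (shift = −log₂FC) following the qualitative patterns such
stress experiments report: every target spikes at 3 h under SA and then
collapses below baseline; EtH/MeJA split the panel into an early-peaking and
a down-then-up group (the CS-like target dips to 12 h and peaks at 24 h
under EtH); cold induces transiently; heat gives a brief bump or sustained
repression.  A dilution-series companion synthesizes standard curves with
exact designed efficiencies (Ct step per level = $\log_{10}b / \log_{10}(1+E)$).

What the generator does **not** emulate: non-Gaussian outliers by default
(a heavy-tail flag exists for robustness experiments), missing-at-random
dropout, inter-gene correlated regulation beyond the designed shifts,
technical replicates, or fluorescence-level artifacts (primer dimers, melt
behavior).  Passing the recovery tests therefore demonstrates correctness
of the algorithms under the declared generative model, not performance on
any particular real dataset.

## Problem sizes and numerical choices

The recovery study runs 100 seeded datasets of 12 candidates × 90 samples —
enough to resolve the ≥95% / ≥99% recovery targets while keeping the whole
acceptance suite in seconds; the null-calibration study uses 1000 trials of
3 + 3 replicates.  All SDs are sample SDs (ddof 1).  All rankings use
average ranks on ties, with lexicographic gene order only as a final
deterministic tiebreak in outputs and removals.  Equality thresholds are
strict where the field's rules are strict ($V < 0.15$, SD $> 1$); the
acceptance tests probe both sides of each boundary (0.149/0.151 and
1.0/1.0001).  The long-CSV writer emits shortest round-trip float reprs and
the readers parse with correctly-rounded conversion, so write→read is
bit-exact.

## Pipeline and provenance

`run_pipeline` executes read → screen → (optional) calibration → aggregate →
per-subset stability (the five per-treatment subsets plus a pooled "all"
group by default — group membership is explicit in config rather than
guessed) → consensus → best pair → expression profiles per configured
normalizer, writing plain TSV only.  Reports embed the config, a SHA-256
digest of its analysis-relevant fields, seed and package version; reruns
from the recorded config are byte-identical, which the tests verify.
Thresholds actually applied are logged so a report is auditable.

## Known limitations

* The NormFinder variant is a documented re-derivation, not a line-for-line
  port of the original tool; only rank-level agreement should be expected.
* geNorm cannot order its final pair; both genes share rank 1.5, and
  consensus ranks inherit that coarseness.
* Efficiency correction assumes one efficiency per primer across all
  samples; per-sample efficiency estimation (LinRegPCR-style) is out of
  scope.
* The expression module profiles relative quantities only; absolute
  quantification is out of scope.
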