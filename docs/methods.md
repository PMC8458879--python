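# Methods

`cernamut` implements an integrative somatic-mutation / transcriptome
analysis for tumor cohorts (its defaults are tuned to a pancreatic
adenocarcinoma setting): mutation-landscape statistics, expression-based
driver testing, driver co-expression networks, detection of lncRNA
mutations that perturb miRNA response elements (MREs), rank-based
enrichment, and Cox survival risk modelling. This note records the
models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Mutation landscape

Somatic calls are read from MAF-like TSVs (1-based inclusive
coordinates; insertions anchored at the base before the insertion).
Substitution spectra are pyrimidine-normalized into the six classes
C>A, C>G, C>T, T>A, T>C, T>G; A<->G and C<->T are transitions,
everything else a transversion. The gene x sample mutation matrix
counts every mutation but the carrier mask counts a sample once per
gene, because the driver test downstream compares carrier against
non-carrier *samples*. Genes mutated in fewer than `min_carriers = 2`
samples are dropped. Carrier co-occurrence between gene pairs uses
Fisher's exact test on the 2x2 carrier table (two-sided), with
Benjamini–Hochberg adjusted p reported alongside the raw p; perfect
co-occurrence reports an infinite odds-ratio sentinel. Exact-test
p-values are discrete and conservative for small cohorts; they approach
uniformity under the null only for large carrier margins (see
"Calibration" below).

## Driver genes

A driver here is a gene whose expression differs between mutation
carriers and non-carriers. The test is a two-sided Welch t-test on
log2(x+1)-transformed expression; the fold change is reported on the
linear scale as (mean_mut + 1) / (mean_wt + 1). The pseudocount guards
zero means and makes label swapping invert the fold change exactly. A
gene is flagged when p < 0.05 and |log2 FC| > log2(1.5); both cutoffs
are parameters. Flagging deliberately uses the raw p (the protocol this
reproduces does); BH-adjusted p is an extra column. The Welch form is
the default because carrier groups are usually much smaller than
non-carrier groups; the equal-variance form and a linear-scale test are
switches. Results are sorted by |log2 FC| descending.

## Co-expression networks

Edges connect a driver to a partner when Pearson |r| > 0.5 and p < 0.01
(p from t = r·sqrt(n-2)/sqrt(1-r^2) on n-2 df). Only driver–partner
pairs are tested (a union of driver stars), not partner–partner pairs;
duplicate driver–driver edges are kept once. Hubs are the maximum-degree
nodes, ties reported as a lexicographic set. Zero-variance genes are
skipped rather than producing undefined correlations.

## MRE disruption (regulation units)

Each lncRNA mutation is relocated into transcript coordinates
(strand-aware: on the minus strand transcript position 1 is the
3'-most genomic base). A window of 21 nt upstream and 7 nt downstream
of the mutated base is extracted in wild and mutant form; flanks are
truncated at transcript ends and the truncation recorded. Indels use
the anchor base as the site: inserted bases appear between the anchor
and the downstream flank, deleted bases are absent from the mutant
window.

Two independent scorers judge miRNA binding:

* **Seed-weighted local alignment.** The reversed miRNA is aligned to
  the window by affine-gap local dynamic programming (Watson–Crick pair
  +5, G:U wobble +2, mismatch −3, gap open −8, gap extend −2), with
  pair contributions at miRNA seed positions 2–8 scaled by 4. Gap
  penalties are not seed-scaled. Each site carries a duplex free-energy
  surrogate: bundled Watson–Crick RNA·RNA nearest-neighbor stacking
  terms (Turner 2004 set, 16 dinucleotide steps; see
  `data/rna_stack_energies.tsv`) summed over consecutive paired
  positions, with +0.45 kcal/mol per helix end closing on an A·U pair;
  wobble-containing stacks, mismatches and gaps contribute 0 — a
  deliberate, conservative subset. Non-overlapping suboptimal sites are
  returned best-first above a score floor (default 10).
* **Seed-site context scorer.** Canonical sites (8mer, 7mer-m8,
  7mer-A1, 6mer) are detected by exact complementarity to miRNA
  positions 2–7, the m8 pair and the target-adenine rule opposite
  position 1. The context score adds a site-type term (−0.35, −0.20,
  −0.12, −0.05), a 3'-supplementary term (−0.01 per consecutive pair
  over miRNA 13–17, floored at −0.05) and a local-AU term (−0.10 × AU
  fraction of the window outside the site). More negative is stronger.

A call is **reliable** when it passes either scorer's full threshold
set — alignment score > 160 with energy < −20 kcal/mol, or context
score < −0.4 (the thresholds are applied verbatim; the scorer internals
are this package's own, documented surrogates, not re-creations of any
external tool). An intersection mode requiring both scorers is a
configuration switch; `passed_by` records provenance either way. The
wild-to-mutant change of the best reliable site (max alignment score,
ties by lower energy then leftmost) is classified as **gain**
(mutant-only site), **loss** (wild-only), **up**/**down** (both present,
strictly higher/lower mutant score within a 1e-9 tie tolerance);
`unchanged` pairs produce no unit. Swapping wild and mutant maps
gain<->loss and up<->down by construction. Units join a validated
miRNA→mRNA target table into a mutation–lncRNA–miRNA–mRNA network.

## Enrichment

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum: hits
increment by |w|^p / Σ_set |w|^p (default exponent p = 1), misses
decrement by 1/(N − N_set); the enrichment score is the signed maximum
deviation. Two ranking schemes mirror the analysis protocol:
−log10(p) from the driver tests (zero p clamped to the smallest
positive double) and co-expression coefficients. The permutation null
resamples same-size gene sets from the ranked universe —
phenotype permutation is impossible because the input is a precomputed
ranking — and p = (1 + #{|ES_null| ≥ |ES|}) / (1 + n_perm).
Over-representation uses the upper-tail hypergeometric p with BH
adjustment across sets. Gene sets are read from GMT text.

## Survival

Expression enters survival models as log2(x+1), standardized per gene
before penalized fitting so the L1 path shrinks comparable scales. The
screen is per-gene univariate Cox (p < 0.05); selection is
L1-penalized Cox along a 50-point log-spaced lambda path
(coordinate descent via scikit-survival), with lambda chosen by
Verweij–van Houwelingen cross-validated partial likelihood and the
one-standard-error rule — the sparsest lambda within one fold-SE of the
CV optimum. The CV-minimum alone overselects: in the bundled
support-recovery simulation it admitted ~25 of 50 noise genes, while
the 1-SE rule keeps all 5 planted genes with at most a handful of
false positives. The final multivariate Cox fit (lifelines; Efron tie
handling, immaterial for continuous times) yields the risk model
score(x) = Σ beta_i · x_i, linear with no intercept.

The published 8-gene pancreatic-adenocarcinoma model
(0.65·SLC30A1 − 0.84·RBM10 − 0.27·PNPLA6 + 0.36·DSG2 − 0.21·CHML +
0.54·DLGAP5 − 0.02·TTLL6 − 0.08·PDE4DIPP5) ships as a fixture and is
applied on the same expression scale. Cohorts are split 70/30
(train size = round(0.7·n), seeded shuffle) and each part dichotomized
at its own median risk score (> median = high; the median sample goes
low). Group separation is Kaplan–Meier + two-sided log-rank.
Discrimination is the cumulative/dynamic time-dependent AUC: cases are
events by time t, controls are samples observed past t, samples
censored before t are excluded, and the AUC is the Mann–Whitney
probability that a case outscores a control (ties count ½). The
default evaluation grid is six uniform time points over 6–18 months:
180, 253, 326, 399, 472, 545 days (configurable).

## Synthetic cohort

The generator emulates the cohort the pipeline expects, with planted
truth for every stage. Defaults: 180 samples, 300 genes, 8 drivers at
log2 FC = 2 applied multiplicatively to ~30% carriers (at least 2, so
planted drivers survive the carrier filter), Poisson(3) passenger
mutations per sample, 12 lncRNAs carrying one planted MRE mutation each
(three per state), 10 random 22-nt miRNAs, exponential survival with
baseline hazard 1/500 per day (median ~1 year) driven by coefficients
on two designated genes, and ~30% independent uniform censoring whose
upper bound is calibrated by bisection to the requested fraction.
Expression is log-normal noise (sigma = 0.35 on the log scale) around
log-normal gene baselines. Stage labels are uniform over I–IV and
uncoupled from risk by default.

MRE planting is constructive and self-verifying: a site complementary
to miRNA positions 1..k is written into the window, gain/loss break the
base opposite seed position 4 (replacing it with the miRNA base itself,
which can neither Watson–Crick nor wobble pair), up/down perturb the
base opposite position 1 (outside the seed, so both alleles keep a
reliable site and the score change is strict). k is searched (17 down
to 12 for gain/loss so the broken side fails both thresholds and the
intact side passes at least one; full miRNA length for up/down) and
every candidate is verified through the real extraction and scoring
path before being accepted. lncRNA transcripts are single-exon plus
strand except the last, a multi-exon minus-strand fixture that
exercises the coordinate mapping; chromosome sequences are written so
the spliced transcript round-trips through the exon map.

What the generator does **not** emulate: trinucleotide mutational
signatures, copy-number events, read-level noise, correlated
co-expression structure beyond the planted effects, miRNA expression,
or stage–risk coupling (available as a configuration, off by default).
Passing tests therefore demonstrate correctness of the statistical
machinery and the closed loop on planted effects — not biological
discovery performance on real cohorts.

## Calibration and numerical choices

* Determinism: every stochastic step takes an explicit seed; a fixed
  `SimConfig` reproduces byte-identical cohort files.
* Null calibration: driver-test, correlation, log-rank and GSEA
  p-values are checked for approximate uniformity under simulated nulls
  (KS at alpha = 0.01, ≥500 replicates). Exact-test (Fisher)
  co-occurrence p-values are discrete with an atom at 1; uniformity is
  asymptotic, so calibration is checked at large carrier margins
  (n = 4000) and, at cohort scale (n = 200), only the conservative
  direction P(p ≤ a) ≤ a is asserted — the exact test never
  over-rejects.
* Ties: best-site selection breaks ties by lower duplex energy then
  leftmost site; ranking ties break by gene id; the median risk sample
  goes to the low group; hub ties are reported as a set.
* Degenerate inputs: zero-variance covariates, all-censored groups,
  empty gene-set overlaps and empty networks are flagged or returned
  empty rather than erroring the pipeline; ref/alt mismatches against
  the transcript sequence are hard errors naming the position.
* Problem sizes in the test suite (500 samples for Cox recovery, 400
  for lasso support recovery, 200 for driver recovery, 500 replicates
  for calibration) were chosen as the smallest sizes at which the
  asymptotic behaviour under test is expected to hold.

## Known limitations

* The duplex-energy surrogate ignores loop entropies, dangling ends and
  wobble stacking; it is a reproducible desk-scale stand-in for a full
  thermodynamic folding calculation, adequate for ranking wild against
  mutant windows that differ by one edit.
* Minus-strand indel windows anchor at the 3'-most genomic base of the
  reference span; complex substitutions (multi-nucleotide ref and alt
  of different lengths) are treated as replacement edits.
* The alignment scorer reports at most three non-overlapping sites per
  window; windows are at most 29 nt, so this is not a practical limit.
* No NES-style normalization of enrichment scores across set sizes;
  compare p-values, not raw ES, across sets.
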