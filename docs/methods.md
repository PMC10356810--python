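# Methods

## The model

Somatic mutations observed in sequenced tissue are the product of two
processes: the mutational process, which proposes variants at rates
governed (to first order) by the trinucleotide context of each site, and
selection, which makes fitness-increasing variants more likely to expand
into detectable clones. `missel` models the first process explicitly and
treats any departure of the observed variant distribution from it as
evidence of selection on whatever feature the departure aligns with.

The neutral null is deliberately simple: the probability of observing a
given possible missense variant is proportional to the spectrum rate of its
(context, alternate) channel, normalised over the analysed region. No
site-level covariates (replication timing, expression, chromatin) enter the
model; the assumption is that within a single coding region a 192-channel
context model captures the mutational heterogeneity that matters. Tests are
therefore *within-region* comparisons — a feature is tested against the
rest of the same region, never against the exome.

## Mutational spectrum

* 192 strand-specific channels: 4 (5′ base) × 4 (ref) × 4 (3′ base) × 3
  (alt), contexts read in the direction of transcription. No collapsing to
  96 pyrimidine-context channels, because transcribed strands are not
  exchangeable under transcription-coupled processes.
* Denominators count context occurrences once per selected transcript
  (longest CDS per gene; ties broken lexicographically on transcript id).
  By default only genes carrying at least one observed exonic mutation
  contribute, mirroring how such spectra are estimated in practice;
  `restrict_to_mutated_genes=False` uses every supplied transcript.
* Terminal CDS positions take their missing neighbour from a supplied
  one-base flank; internal positions use spliced CDS neighbours. Flanks are
  part of the transcript input, so the module is genome-independent. If the
  flanking base at an exon junction is drawn from the spliced neighbour
  rather than the intron, a handful of junction channels may be
  misattributed; with typical exon lengths this affects a sub-percent
  fraction of sites.
* Positions whose trinucleotide contains a non-ACGT base are excluded from
  numerator and denominator alike.
* A mutation merged from k clones contributes k to the numerator
  (`count_weighted=False` gives unique-site spectra). The conservation
  identity Σ rate × context_count = Σ counts holds exactly and is tested.

## Null catalogue

Every CDS position yields three possible variants, annotated with the
standard genetic code. The null is nucleotide-level: two nucleotide changes
producing the same amino-acid substitution stay distinct entries, and
amino-acid-level scores (∆∆G) are copied onto each. Probabilities are
restricted to a consequence class — missense by default; stop-loss is its
own class and never enters missense analyses — and renormalised to sum 1
(checked to 1e-12 after every filtering or exclusion step). Entry order is
deterministic: position ascending, alternate bases A<C<G<T.

## Feature scores

* **∆∆G** (kcal/mol): parsed from FoldX PositionScan output. Two dialects
  are accepted: scanning-output rows `<label>\t<ddg>` with labels of the
  form wild-type aa + chain + residue + mutant aa (`EA455K  2.31`), and a
  comma-separated two-column fallback. Variants with ∆∆G strictly greater
  than 2 kcal/mol are classed destabilising; the threshold is a parameter
  and a sweep over 1–4 kcal/mol is exercised in the tests.
* **Residue sets**: Boolean membership; the NOTCH1/NOTCH2 EGF11–12
  interface and calcium-binding sets ship as package data and are guarded
  by a checksum test.
* **Distance**: minimum Euclidean distance between the residue's heavy
  atoms and a declared target selection (ligand peptide, DNA, substrate).
  Heavy atoms only — crystal structures typically lack hydrogens, and
  including them where present would bias covered residues. "Within 8 Å"
  comparisons are inclusive (≤). Residue-numbering offsets between
  structure and protein coordinates are explicit configuration, never
  inferred.
* Entries without structure coverage stay NaN ("unscored") and are dropped
  from **both** null and observed by any test using that feature, with the
  dropped observed count reported on the result.

## Statistical tests

* **Binomial** (Boolean features): observed feature-positive count k out of
  n against Binomial(n, p₀), p₀ the feature's summed null probability.
  Two-sided p by the minimum-likelihood convention: sum of probabilities of
  all outcomes no likelier than k. Outcomes within a relative 1e-10 of the
  observed outcome's probability count as ties, so exactly symmetric cases
  (p₀ = ½) behave identically in exact and floating arithmetic. The p-value
  is floored at the observed outcome's own probability (computed in log
  space when the pmf underflows) and never reported as 0. The 95% CI on the
  expected count is the equal-tailed pair of Binomial(n, p₀) quantiles.
  Exact type-I calibration at the tested operating point (n=100, p₀=0.3,
  α=0.05) is 0.0498.
* **Monte Carlo** (continuous scores): n_draws samples of size n with
  replacement from the null probabilities; recurrent mutations are
  independent draws (each clone is an independent origination; unique-site
  mode is available upstream). Default statistic is the sample median, for
  reporting parity with expected/observed medians; `mean_cdf` (mean of
  mid-CDF-transformed scores) is available for heavy-tailed scores and is
  the better-calibrated choice at small n, where the median's discreteness
  makes the two-tailed p conservative (never anti-conservative — both
  behaviours are tested). p = min(1, 2·(min tail + 1)/(n_draws + 1));
  default n_draws = 100,000, giving a floor of 2e-5. A seed is mandatory
  and recorded in the result. Sampling is chunked at ~5e6 cells per block
  to bound memory.
* **CDF shift**: F(x) = P(X<x) + ½·P(X=x) under the null, computed with
  exact ties on score values, so E_null[F] = ½ to machine precision. The
  shift is mean observed F minus mean null F; it is algebraically confined
  to [p_min/2 − ½, ½ − p_max/2] ⊂ [−0.5, 0.5] and approaches ±0.5 only in
  the vanishing-mass limit. A 1e-12 tolerance absorbs float summation noise
  at the extremes before the bound is enforced. Per-structure shifts are
  aggregated per gene by unweighted mean; correlation with log truncating
  dN/dS uses Pearson's r with the t-distribution two-tailed p, excluding
  non-positive dN/dS values with a warning.

## Layering

Each layer tests its feature on the current (cumulatively excluded) null
and observed, then removes its exclusion predicate from both and
renormalises. Entries matching several layers are excluded at the first
matching layer; the order is explicit analyst configuration (for the
NOTCH1-style analysis: destabilising first, then interface, then calcium,
matching the order in which the stronger categories are established).
Predicates are pandas-eval expressions over feature columns (comparisons
and Boolean operators). Layers reaching fewer than 5 observed mutations are
flagged `underpowered`; a layer that empties the data halts the run with
partial results and an explicit status rather than failing silently.

## Synthetic data

The generators emulate the study conditions so the pipeline is testable
without downloads:

* transcripts: random CDS, ATG start, no internal stops, configurable GC
  bias, one-base flanks;
* spectra: lognormal channel rates (σ = 1 by default — heterogeneity of the
  same order as real tissue spectra);
* mutation sets: multinomial draws with weights = null probability × the
  product of matching layer enrichment factors (factors compose
  multiplicatively across overlapping layers; the canonical `fig1` scenario
  uses factors 3 and 2 on disjoint ~20% null-mass partitions, drawn as
  contiguous residue blocks);
* ∆∆G: two-component Gaussian mixture (benign mode N(0.3, 0.6), tail
  N(3.5, 1.2), tail weight 0.25; "core" residues may draw the tail with
  elevated probability), one value per amino-acid change shared across
  nucleotide paths;
* structures: ideal α-helical Cα trace (2.3 Å radius, 1.5 Å rise, 100°
  twist) with a pseudo-ligand placed on a radial ray at analytically known
  distance.

What the generators do **not** emulate: clone spatial dynamics and merging,
coverage-dependent detection, signature mixtures beyond a single 192-channel
spectrum, correlated ∆∆G along the chain, or real side-chain geometry.
Passing tests therefore demonstrate the statistical machinery — calibration,
masking/unmasking, bound attainment — not the biological fidelity of any
particular dataset.

## Problem sizes used in the shipped tests

Type-I calibration uses 10,000 neutral replicates at n=100, p₀=0.3; the
masking analysis 1,000 replicates of the `fig1` scenario at n=300; the
spectrum round trip 10,000 mutations over twelve 400-codon transcripts; the
Monte-Carlo-vs-enumeration checks 100,000 draws on catalogues of ≤5
entries; the CDF-shift bound sweep ~10,000 random observed sets over ~50
catalogues of 10–1000 entries. Monte Carlo calibration in the unit tests is
scaled to 300 replicates × 2,000 draws per statistic.

## Known limitations

* The null ignores site-level mutation-rate covariates beyond trinucleotide
  context; regions with strong internal rate gradients would need a richer
  spectrum.
* Exact binomial two-sided conventions differ between software; the
  minimum-likelihood convention used here matches `scipy.stats.binomtest`
  and is cross-checked against it, but confidence-interval conventions
  (equal-tailed quantiles of the expected count) are one of several
  reasonable choices.
* The Monte Carlo median test is conservative for small n because the
  sample median is discrete; use `mean_cdf` when calibration at small n
  matters.
* Multiple-testing correction across genes or features is intentionally out
  of scope; p-values are reported raw.
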