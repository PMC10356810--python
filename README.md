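# missel

Detection of selection of structural and functional features among somatic
missense mutations.

Deep sequencing of physiologically normal tissues (oesophagus, skin) reveals
clones carrying somatic mutations under positive selection. For a gene like
*NOTCH1*, the selected missense mutations are not spread uniformly: they
concentrate on destabilising substitutions (high ∆∆G), on ligand-binding
interface residues, and on calcium-binding sites. `missel` quantifies this
kind of feature-level selection for users analysing somatic mutation
catalogues together with protein structures: it asks, for any structural or
functional feature, whether the observed mutations are enriched (or
depleted) on that feature relative to what the mutational process alone
would produce.

## Method

**Neutral null model.** For each dataset a strand-specific trinucleotide
spectrum is estimated: for every context 5′-N·X·N-3′ (read in transcription
direction) and alternate base *a*, the rate

&nbsp;&nbsp;&nbsp;&nbsp;r(N·X·N → a) = (observed mutations of that channel) / (context occurrences in the included transcripts),

giving 192 channels. Every possible single-nucleotide missense variant of a
region is enumerated and assigned probability proportional to its channel
rate, normalised over the region — the expected distribution of mutations
under no selection.

**Feature tests.** Boolean features (interface membership, ∆∆G > 2 kcal/mol,
within 8 Å of a substrate) are tested with an exact two-tailed binomial
test of the observed feature-positive count *k* against Binomial(*n*, *p₀*),
where *p₀* is the summed null probability of feature-positive variants
(two-sided by the minimum-likelihood convention; equal-tailed binomial
quantiles give the 95% CI on the expected count). Continuous scores (∆∆G,
distance to a binding partner) are tested with a two-tailed Monte Carlo
test: samples of size *n* are drawn from the null, the sample median is
compared with the observed median, and the smaller tail is doubled (with a
+1 pseudo-count, so p ≥ 2/(n_draws+1)).

**Exclude-and-retest layering.** Strong selection of one category masks
weaker selection of another. Removing an already-explained category from
*both* the null (renormalising) and the observed data and re-testing
unmasks the weaker signal; iterating over ordered layers classifies the
mutation set and leaves a residual of unexplained mutations.

**∆∆G CDF shift.** For gene-level classification each variant's ∆∆G is
mapped to its mid-distribution CDF value under the null,
F(x) = P(X &lt; x) + ½·P(X = x), whose null mean is exactly ½. The shift —
mean observed F minus ½ — lies in [−0.5, 0.5]: positive values mean
selection *for* destabilising mutations (fitness-suppressor pattern,
loss-of-function favoured), negative values selection against them
(fitness-enhancer pattern). Per-structure shifts are averaged per gene and
can be correlated with the log truncating dN/dS ratio.

## Worked example

The synthetic-data module plants known selection so the whole pipeline can
be exercised without external data. Here a "strong" feature is enriched
threefold and a disjoint "weak" feature twofold (20% of the region each),
with 300 observed mutations:

```python
import missel as ms

transcript = ms.simulate_transcript(100, seed=1)
spectrum = ms.random_spectrum(2)
cat = ms.build_null(ms.enumerate_snvs(transcript), spectrum)
cat = ms.plant_partition_features(cat, seed=3)     # adds "strong"/"weak" partitions
cat.entries["ddg"] = ms.simulate_ddg(cat, seed=4)
obs = ms.simulate_mutations(cat, ms.fig1_scenario(300), seed=5)

masked = ms.binomial_feature_test(obs, cat, "weak")
print(f"weak feature, no exclusion: expected {masked.expected_summary:.1%}, "
      f"observed {masked.observed_summary:.1%}, p = {masked.p_two_tailed:.2g}")

out = ms.layered_analysis(cat, obs, [ms.LayerSpec("strong"), ms.LayerSpec("weak")])
for r in out.results:
    print(f"layer {r.feature!r}: expected {r.expected_summary:.1%}, "
          f"observed {r.observed_summary:.1%}, p = {r.p_two_tailed:.2g}, n = {r.n}")
print(f"residual: {out.n_residual}/{out.n_total} mutations unexplained")

shift = ms.cdf_shift(obs, cat, "ddg")
print(f"ddG CDF shift: {shift.shift:+.3f} (n = {shift.n})")
```

prints

```
weak feature, no exclusion: expected 20.3%, observed 21.7%, p = 0.57
layer 'strong': expected 20.2%, observed 37.7%, p = 3.2e-12, n = 300
layer 'weak': expected 25.4%, observed 34.8%, p = 0.0043, n = 187
residual: 122/300 mutations unexplained
ddG CDF shift: -0.002 (n = 300)
```

Tested directly, the weak feature looks neutral (21.7% observed vs 20.3%
expected) because the strong enrichment dilutes it. After the strong
category is excluded from null and observed alike, the weak feature's
enrichment (34.8% vs 25.4% expected among the remaining 187 mutations)
becomes significant — the masking/unmasking behaviour the layering
procedure exists for. The ∆∆G CDF shift is ≈ 0 here because the planted
partitions are independent of the synthetic ∆∆G column.

A command-line interface mirrors the library
(`missel simulate|spectrum|catalogue|annotate|test|layer|shift`); every
output file carries a provenance header (version, seed, input checksums).
The residue sets used in the NOTCH1/NOTCH2 analyses (ligand-binding
interface and calcium-binding residues of EGF repeats 11–12) ship with the
package (`missel.io.load_bundled_residue_sets()`).

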