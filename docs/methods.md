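# Methods

This note records the statistical model behind each stage, the generator's
scope, and the numerical choices that are the package's own rather than
forced by the problem.

## Quantification and filtering (`quant`)

FPKM[g, s] = count[g, s] · 10⁹ / (length_bp[g] · total_count[s]). The
*coexpressed* set keeps genes whose group-mean FPKM is strictly positive in
all four groups (`per_sample=True` switches to the stricter every-library
rule). All downstream stages operate on this set, so every reported
percentage has the same denominator.

## Differential expression (`detest`)

A negative-binomial exact test for two small groups of count libraries:

- **Size factors** — median across genes of the ratio of each library to the
  per-gene geometric mean, computed over genes with no zero counts; if no
  such gene exists the estimator falls back to total-count scaling with a
  warning. The estimator assumes most genes are unchanged between the
  groups; matrices in which the majority of genes shift in one direction
  will be partially normalised away (this is inherent to the method, and the
  test suite constructs its planted-signal fixtures accordingly).
- **Dispersion** — method-of-moments per gene pooled over both groups,
  α = (s² − m·E[1/s_j]) / m², then a mean-rank trend over 20 bins. The bin
  summary is the bin **mean** of the moment estimates, smoothed by a running
  median across bins; the final dispersion is max(raw, trend). With three
  replicates the moment estimator is strongly right-skewed, and a median
  trend sits systematically below the true dispersion: measured on null
  simulations it inflated the far tail (≈1.8× nominal FDR), whereas the bin
  mean restores control (≈0.3–0.9× nominal pooled over ten seeds) at
  unchanged power (0.986 at |log2FC| = 3). This makes the estimated-
  dispersion path deliberately conservative at desk scale.
- **P-values** — conditional on the two group totals, the probability of
  each split is negative-binomial on both sides; the two-sided p-value sums
  the probabilities of splits *strictly less probable* than the observed one
  plus **half** the observed atom (mid-p). The classic atom-inclusive rule
  is measurably sub-uniform under the null (Kolmogorov–Smirnov p ≈ 2·10⁻³
  at 5,000 null genes even with the dispersion known), which breaks both
  calibration checks and FDR accounting; mid-p passes the KS uniformity
  check across seeds (p 0.23–0.80). For totals above 20,000 the conditional
  distribution is replaced by a normal approximation with continuity
  correction.
- **Calls** — Benjamini–Hochberg FDR (delegated to
  `statsmodels.stats.multitest.multipletests`) with the dual rule
  FDR < 0.001 **and** |log2 fold change| > 1 (fold changes on means + 1).
  The category stage reuses the fitted tests at FDR < 0.005.

Calibration checks run the known-dispersion path (the generator's dispersion
passed through) to isolate the exact test itself from the conservative
moment estimation. Empirical FDR is assessed **pooled** across ten seeds: at
a nominal 0.001 with ~500 discoveries per seed, a single false discovery in
one seed already gives 0.002, so a per-seed bound is not statistically
meaningful at this scale.

## Twelve-category classification (`eldclass`)

The decision table maps the sign trio (d_HA, d_HB, d_AB) to categories I–XII
plus NO_CHANGE = (0, 0, 0). The remaining 14 of the 27 triples are logically
inconsistent under dual-threshold calling (e.g. the hybrid above one parent
and below the other while the parents are called equal) and are reported as
AMBIGUOUS instead of being silently merged into a neighbouring class.
Group labels: I–II BSB-ELD, III–IV YB-ELD, V–VI additivity, VII–IX
transgressive up, X–XII transgressive down. Asymmetry between the hybrids
(ELD direction; up vs down transgression) is a two-sided Fisher exact test
(`scipy.stats.fisher_exact`, minimum-likelihood rule).

## Mid-parent dosage tests (`dosage`)

MPV1 = χ(BSB) + ½χ(YB), MPV2 = ½χ(BSB) + ½χ(YB), MPV3 = ½χ(BSB) + χ(YB),
built replicate-paired from the parents' FPKM (equal parental replicate
counts required). Hybrid replicate r is compared with MPV replicate r by
fold change only, log2((h + ε)/(MPV + ε)) with ε = 0.1 FPKM, called at
|log2| > 1; gene-level calls require a consistent direction in the mean over
pairs. `dosage_summary` reports up/down counts per profile and flags a
hybrid as `biased_toward_MPV2` when its |up − down| imbalance is smallest
against MPV2 — the dosage-compensation signature.

**Limitation.** A genome-wide dosage effect (every gene scaled by 1.5×) is
invisible after per-library normalisation, because the library total scales
by the same factor: FPKM, and any other within-sample normalisation, cancels
it exactly. The compensated/additive distinction is therefore observable in
normalised data only through the *relative* weighting of the MPV profiles
(deficit vs MPV1/MPV3 with balance vs MPV2), and the additive mechanism is
verified in the test suite on per-copy abundances directly.

## Ortholog concatenation and trees (`orthosim`)

Reciprocal best hits under `Bio.Align.PairwiseAligner` local alignment
(match 1, mismatch −1, gap open −5, extend −2), with a 15-mer shared-seed
prefilter standing in for a BLAST-style seed step; hits require raw score
≥ 100 and sequence length ≥ 200. Shared orthologs are anchored on BSB,
aligned globally with free end gaps, projected onto the first sample's
coordinates, terminal overhangs trimmed, interior gaps masked to N, cores
shorter than 100 bp dropped, and the cores concatenated in lexicographic
ortholog-id order (determinism; the order is otherwise arbitrary). Identity
is the fraction of matching positions over columns where neither sequence is
N. Trees are neighbour joining (`skbio.tree.nj`) on 1 − identity with
negative branch lengths clamped to zero. Raw identity is used rather than a
maximum-likelihood distance transform; at 2–3 % divergence the difference is
below the reporting precision, and the conclusions drawn from the matrix are
topology-level.

## Generator (`simdata`)

The generator's defaults are the study conditions, fixed before any test
outcome was observed: 3 replicates per group, log-normal baseline means
(log-mean 4, log-sd 1), per-gene log-normal dispersions around 0.05, effect
size 2 on the log2 scale (must exceed the calling threshold of 1), library
size factors uniform on [0.7, 1.3], gene lengths uniform on [300, 3000] bp,
and a category mixture with 71 % NO_CHANGE, maternally biased ELD mass
(18 % BSB-ELD vs 6 % YB-ELD). Each category is realised as an integer
expression level per group times the effect size on the log2 scale, chosen
so that classifying the *noise-free* true means reproduces the generating
label exactly (`classify_noise_free` verifies this identity). Triploid
dosage is `compensated` (3nBY means equal 2nBY means) or `additive` (1.5×).
Sampling is negative-binomial (Poisson below dispersion 10⁻¹²) with a single
seeded generator; `maternal_bias` rescales the maternal ELD categories and
renormalises.

Sequence sets: BSB random, YB by iid substitutions at the configured
divergence (default 0.024, rejected above 0.25 where the p-distance
saturates), hybrids copying a configured source parent (default 2nBY from
YB, 3nBY from BSB) plus 0.002 replicate divergence; optional YB GC bias and
random terminal extensions exercise the trimming and composition code.

**Scope.** The generator makes no attempt to model transcript assembly,
mapping ambiguity, homoeolog cross-mapping, GC/length biases in coverage, or
correlated dispersions; it exists to give every pipeline stage a ground
truth at desk scale (thousands of genes, tens of orthologs), not to imitate
a sequencing run.

## Reference-table checks

The acceptance suite reproduces the arithmetic of the reference dataset's
reported count/percentage tables over its 10,057 coexpressed genes and the
significance of its 2×2 asymmetry tables. Two reported pairs are internally
inconsistent (357 printed as "3.73 %" where 357/10,057 = 3.55 %; 201 printed
as "2.09 %" where 201/10,057 = 2.00 %) and one count appears as both 201 and
199 in different places (201 is used; it matches the stated 2,911 parental-
ELD total). The inconsistent pairs are excluded from the arithmetic check
but their counts are still exercised in the Fisher tables. The linked-
ortholog identity check (0.976 ± 0.003) runs on simulated sequences at the
reference divergence scale through the full pipeline, since the original
sequence supplement is not redistributable inside this repository.
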