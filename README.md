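# polyhybrid

Expression analysis of duplicated genes in interploidy hybrid crosses.

`polyhybrid` implements the complete transcriptome-comparison workflow for a
cross between two divergent fish species — the maternal parent (BSB), the
paternal parent (YB) — and their first-generation allodiploid (2nBY) and
allotriploid (3nBY) hybrids, three biological replicates per group. The same
machinery applies to any two-parent/two-hybrid design; the four group labels
are conventions, not hard-coded biology.

## The science

When two divergent genomes meet in one nucleus, the expression of each
duplicated gene pair can follow either parent, sit between them, or escape
the parental range entirely. The package answers four questions about such a
cross:

1. **Which genes are differentially expressed?** Counts are converted to
   FPKM, genes silent in any group are removed (the *coexpressed* set), and
   every pairwise group contrast is tested with a negative-binomial exact
   test (median-of-ratios size factors, moment dispersion estimates with a
   smoothed mean-rank trend, mid-p two-sided p-values, Benjamini–Hochberg
   FDR). A gene is called at FDR < 0.001 and |log2 fold change| > 1.
2. **Which parent does each hybrid gene follow?** Each gene's trio of signed
   calls — hybrid vs BSB, hybrid vs YB, BSB vs YB, at the category-stage
   cutoff FDR < 0.005 — is binned into twelve expression categories:
   maternal expression-level dominance (BSB-ELD, categories I–II), paternal
   ELD (III–IV), additivity (V–VI), transgressive up (VII–IX) and
   transgressive down (X–XII), plus NO_CHANGE and AMBIGUOUS. Asymmetry
   between the hybrids is tested with Fisher's exact test.
3. **Is the extra genome copy dosage-compensated?** Each hybrid's FPKM is
   compared, replicate-paired, against three in-silico mid-parent profiles
   built from the parents' values: MPV1 = χ(BSB) + ½χ(YB), MPV2 = ½χ(BSB) +
   ½χ(YB), MPV3 = ½χ(BSB) + χ(YB), modelling BBY, BY and BYY genome doses. A
   triploid whose expression stays balanced against the diploid profile
   (MPV2) while sitting below the triploid-weighted profiles is
   dosage-compensated.
4. **Which parental genome does each hybrid's transcriptome resemble?**
   Orthologs shared by all eight samples are found by reciprocal best hits
   under affine-gap local alignment, trimmed to a common core by global
   alignment, concatenated in deterministic order, and summarised as a
   pairwise identity matrix and a neighbour-joining tree.

A ground-truth simulator (`simdata`) generates negative-binomial count
matrices with known per-gene category labels, configurable triploid dosage
mode (compensated or additive), and parent/hybrid ortholog sequence sets at
a chosen divergence — so every stage of the pipeline can be checked against
a known answer.

## Quick start

Run the full pipeline on simulated data (any stage also accepts real TSV /
FASTA inputs — see `polyhybrid run-all --help`):

```bash
$ polyhybrid run-all --seed 42 --out demo
...
stages run: quant, detest, eld, dosage, ortho
```

`demo/report.txt` then contains, among other tables:

```text
polyhybrid run (seed 42)

coexpression filter: 2000 of 2000 genes retained (100.00%)

DEGs 2nBY vs BSB: 192 (9.60%) — 93 up (4.65%), 99 down (4.95%)
DEGs 2nBY vs YB: 421 (21.05%) — 191 up (9.55%), 230 down (11.50%)
...
ELD 2nBY: BSB_ELD=349 (17.45%), YB_ELD=117 (5.85%), ADDITIVITY=30 (1.50%),
          UP=26 (1.30%), DOWN=23 (1.15%), NO_CHANGE=1422 (71.10%), AMBIGUOUS=33 (1.65%)
...
linked orthologs: 60 segments, 42645 bp per sample
```

Every percentage is count / coexpressed-total, rounded to two decimals. The
run also writes per-stage TSVs, a FASTA of the linked ortholog sequences, a
Newick tree, and a machine-readable `summary.json` that validates against
the schema shipped in `polyhybrid.pipeline.report_json_schema()`. Reruns
with the same seed are byte-identical.

### Python API

```python
from polyhybrid import SimConfig, simulate_counts
from polyhybrid.detest import NBDiffExpression
from polyhybrid.eldclass import classify_all

cfg = SimConfig(n_genes=2000, seed=3, nb_dispersion=0.05, effect_log2fc=3.0)
counts, truth = simulate_counts(cfg)

res = NBDiffExpression(counts, "BSB", "YB").fit(fdr_cutoff=0.001, lfc_cutoff=1.0)
print(res.summary())          # contrast, n_up, n_down, cutoffs
res.frame                     # per-gene baseMeans, log2fc, pvalue, fdr, sign

signs = {
    pair: NBDiffExpression(counts, *pair).fit(fdr_cutoff=0.005).sign
    for pair in (("2nBY", "BSB"), ("2nBY", "YB"), ("BSB", "YB"))
}
assign, summary = classify_all(
    signs[("2nBY", "BSB")], signs[("2nBY", "YB")], signs[("BSB", "YB")]
)
print(summary)                # gene counts per ELD group label
```

On this configuration 99.7 % of genes recover their true category and
99.9 % of null genes are classified NO_CHANGE (see the acceptance suite).

## Testing and reproduction

```bash
python -m pytest -q tests/          # full suite, ~1 min on one CPU
```

`tests/test_acceptance.py` holds one test per release criterion: reported
count/percentage arithmetic, Fisher significance of the reported asymmetry
tables, linked-ortholog identity at the reference divergence (0.976 ± 0.003
through the full RBH → trim → link pipeline on simulated sequences), oracle
equivalence of the statistical primitives, ELD parameter recovery with
pooled empirical FDR control, dosage-compensation recovery, and
ortholog-tree recovery.

The headline quantities can be recomputed standalone:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes each quantity as `{"value": ..., "n": ...}`. All randomness in
the script derives from `--seed`; rerunning with the same seed reproduces
the file exactly.

Methodological details, numerical choices and known limitations are
documented in [docs/methods.md](docs/methods.md).
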