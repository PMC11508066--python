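# panelvar

Comparative-genomics toolkit for characterizing what makes one genome
unique within a panel of related genomes. Given a focal breed's assembly
and pairwise difference tables against tens of comparison-breed assemblies,
`panelvar`:

1. **classifies focal-specific variants** — positions where the focal
   allele is found in no other covering genome, subject to a presence rule
   (the position must be covered by enough of the panel, by default
   panel size − 3, mirroring a 30-of-33 rule);
2. **annotates coding effects** — synonymous / nonsynonymous / stop-gain /
   stop-loss / splice-site / intronic / flank / intergenic, with codon and
   amino-acid change strings such as `cgt > ctt` / `r > l at 643`;
3. **tests for enrichment of unique mutations** with an exact binomial tail
   statistic that is free of gene-length bias;
4. **detects long focal-only regions** (intervals covered by zero
   comparison breeds, ≥ 1000 bp) and profiles their perfect tandem-repeat
   and G-quadruplex (G4) content;
5. **generates fully synthetic breed panels** with machine-readable ground
   truth, so every stage is testable end to end without any downloads.

It is aimed at researchers analyzing breed- or strain-specific variation
from whole-genome alignments (livestock and poultry genomics in
particular), and at anyone who needs a length-bias-free enrichment test
for "excess of private mutations" in genes, GO categories, or regions.

## The statistic

Let S be the set of genomic positions where the focal genome differs from
at least one comparison genome, and U ⊆ S the focal-specific subset, with
p = |U| / |S|. For a unit (one gene's missense sites, a GO category's
sites, sites in a gene ± 10 kb window, or a genomic region) with
n = |S′| sites of which k = |U′| are focal-specific,

    p-value = P(X ≥ k),  X ~ Binomial(n, p)
    fold    = (k / n) / p

and the unit is flagged when fold ≥ 2 and p-value < 10⁻³. Conditioning on
n removes the length bias of gene-list enrichment: a long gene gets more
difference sites, but under the null the same *proportion* of them is
focal-specific. No multiple-testing correction enters the flag (a
Benjamini–Hochberg column is emitted as extra information).

## Worked example

Simulate a 600 kb, 12-breed panel with one GO category planted at 8× the
focal-specific rate and three focal-only regions, then analyze it:

```sh
$ cat cfg.yaml
n_breeds: 12
chrom_lengths: {chr1: 400000, chr2: 200000}
n_genes: 100
n_go_terms: 10
n_private_regions: 3
enriched_units: [["GO:0000003", 8.0]]

$ panelvar simulate --config cfg.yaml --seed 11 --out panel
panel written to panel
$ panelvar analyze --panel panel --out results
|S|=6105 |U|=147 regions=3
```

The run found 6105 focal-vs-panel difference positions, of which 147
(2.4%) are focal-specific. The GO-category missense test recovers the
planted unit and nothing else:

```
$ head -3 results/enrichment_GO_MISSENSE.tsv
unit_id     n    k   fold    p_value     passes
GO:0000003  194  28  3.379   2.089e-08   True
GO:0000010  153  8   1.224   0.331       False
```

Of the planted category's 194 missense difference sites, 28 are
focal-specific — 3.4× the panel-wide proportion, with binomial tail
2×10⁻⁸. (The realized fold is below the planted 8× because the planted
sites themselves inflate the genome-wide proportion p at this scale.)

The three planted focal-only regions are recovered with exact boundaries
and their content matches construction (~92% tandem repeats, ~23% G4,
against a genome background of ~3% and ~0.4%):

```
$ head -5 results/region_profiles.tsv
region               chrom  start   end     length  tandem_fraction  g4_fraction
chr1:115383-119716   chr1   115383  119716  4334    0.922            0.232
chr2:102669-104475   chr2   102669  104475  1807    0.916            0.232
chr2:112304-116564   chr2   112304  116564  4261    0.927            0.231
GENOME               *      1       600000  600000  0.030            0.004
```

Per-site effect annotations use the codon/amino-acid string format shown
above (`results/effects.tsv`), e.g. `cag > cgg` / `q > r at 117` for a
nonsynonymous change at protein position 117. `results/specific.vcf`
exports the focal-specific set U; `results/run_report.json` records site
counts at every filter step.

Subcommands `classify`, `annotate`, `enrich`, and `regions` run the
individual stages; `--region-bed` intersects U with externally supplied
region sets (e.g. selection-signature intervals) and reports per-region
counts and density fold changes.

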