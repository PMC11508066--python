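# Methods

This note documents the models, conventions, and design choices behind
`panelvar`: what each stage computes, the assumptions it makes, and what
the synthetic panel generator does and does not emulate.

## Input model and coordinates

The pipeline consumes the product of pairwise whole-genome alignment of a
focal assembly against a panel of comparison assemblies, reduced to two
artifacts per breed:

* a **difference table** (TSV: chrom, pos, focal_allele, breed,
  breed_allele) listing every position where that breed's aligned sequence
  disagrees with the focal genome, and
* a **coverage mask** (BED) of focal intervals the breed's assembly
  aligns to.

The table dialect is *pairwise*: a breed that covers a position but has no
record there matches the focal allele (absence means identity). This is
the natural output of pairwise alignment and is relied on throughout.
Only single-nucleotide substitutions over A/C/G/T are considered; records
with ambiguity codes are dropped with a logged count, and indels are out
of scope.

Public coordinates are 1-based inclusive, matching the
`chr2:122881444:G > T` variant notation; interval arithmetic is 0-based
half-open internally, with conversion only at I/O boundaries (BED stays
half-open on disk).

## Specificity classification

A difference position enters the analysis universe S when at least
`min_breeds` panel breeds cover it (default panel size − 3; with a
33-genome panel this is the 30-of-33 rule — incomplete assemblies should
not veto a site they never aligned to). A position in S is
**focal-specific** (a member of U) when every covered breed carries an
allele different from the focal one; a single covered breed matching the
focal allele makes it ALLELE_SHARED. Multi-allelic positions are allowed:
specificity concerns only the focal allele, not agreement among the
comparison breeds. Each genomic position is counted once regardless of how
many breeds differ there.

## Effect annotation

Gene models are single-transcript multi-exon CDS (GFF3); the first base of
the spliced CDS is codon position 1, so phase is fixed by construction.
The focal genome carries the *derived* allele; the ancestral ("panel")
allele is taken as the most common allele among the covered differing
breeds, with alphabetic tie-break for determinism. Coding changes are
reported panel → focal in the lowercase `ref > alt` codon and
`x > y at P` amino-acid format (1-based protein position).

Classes: NONSYNONYMOUS_SNV, SYNONYMOUS_SNV, STOPGAIN, STOPLOSS,
SPLICE_SITE_VARIANT (the first 2 intronic bases at any exon junction, the
canonical donor/acceptor dinucleotides), INTRONIC, FLANK_10KB (within the
gene ± `flank` window, default 10 kb), INTERGENIC. A site overlapping two
genes is annotated once per gene; the site-level class is the most severe.
STOPGAIN/STOPLOSS are deliberately *not* counted as missense by the
enrichment stage (an `include_stop_in_missense` switch merges them).

Every coding annotation is cross-checked in the test suite against an
independent oracle that substitutes the panel allele into the genome,
re-translates the entire mutant CDS, and diffs the two proteins.

## Enrichment test

With p = |U|/|S|, a unit with n sites and k focal-specific sites scores
`P(X ≥ k), X ~ Binomial(n, p)` exactly (scipy's binomial survival
function; k = 0 gives 1), and effect size `fold = (k/n)/p`. A unit passes
at fold ≥ 2 and p < 10⁻³. The boundary is implemented as fold **≥** 2 (the
inclusive reading; configurable). Conditioning on n is what removes
gene-length bias, and the suite verifies this directly: under the null
with CDS lengths spanning 10×, the pass indicator has rank correlation
|ρ| < 0.2 with gene length.

Four unit-construction modes are provided, each with its own universe:

* GENE_MISSENSE — S = all missense difference positions; S′ = one gene's;
* GENE_FLANK10K — S = positions within any gene ± 10 kb window; S′ = one
  gene's window (the window includes the gene body; a `flank_only` switch
  restricts to the flanks);
* GO_MISSENSE / GO_FLANK10K — the same with units being GO categories,
  restricted to genes carrying at least one GO term. The GO table is used
  flat — no DAG ancestor propagation.

A position contributing to two genes counts once in the mode universe but
in each gene's S′, keeping the null proportion coherent per position.
Units with n = 0 are skipped with a logged reason. Results are sorted by
p-value; a BH-adjusted column is informational only — the pass flag uses
the raw threshold.

A separate region mode scores externally supplied intervals by
`(count/length) / (|U|/genome size)` (density fold) and reports per-region
focal-specific counts.

## Focal-only regions and content profiling

Focal-only regions are maximal intervals covered by **zero** comparison
breeds' masks, reported at length ≥ 1000 bp. Detection uses masks only;
sequence content is used only for profiling.

* **G4 motif**: `G{3,} N{1,7} G{3,} N{1,7} G{3,} N{1,7} G{3,}` on both
  strands (run length and loop cap configurable); loops may contain G but
  a literal `N` base never matches. The reported fraction counts bases
  covered by the union of *all* motif occurrences — per-base semantics
  computed by a memoized maximal-end parse, so overlapping occurrences are
  handled exactly (non-overlapping leftmost matching would undercount).
* **Tandem repeats**: perfect arrays only, unit length 1–50, total array
  length ≥ max(2 × unit, 10) bp, found by periodicity scan
  (s[i] = s[i+u]); a trailing partial copy extends an array. Approximate
  (TRF-style) repeats are a non-goal.

The two annotations are computed independently; a base may count in both
fractions, so the two percentages may sum past 100%.

## Synthetic panel generator

The generator emulates, at desk scale, a panel of breeds descended from a
common ancestor with the focal branch carrying extra private substitutions:

* **Phylogeny**: star topology — each comparison breed differs from the
  focal genome independently. Tree-structured allele sharing is not
  modeled; it is unnecessary for exercising the specificity logic, which
  only asks "does any covered breed match the focal allele".
* **Genome**: i.i.d. bases at GC 0.42 (chicken-like). Default ~1 Mb over
  three chromosomes; real genomes are ~1000× larger, so absolute counts
  scale accordingly but rates and proportions do not.
* **Genes**: 200 multi-exon CDS (2–6 exons, CDS 300–1800 bp, introns
  60–400 bp with canonical GT..AG), half on the minus strand, placed
  without overlap by randomly partitioning free space. Each gene receives
  1–3 of 20 flat GO terms.
* **Difference sites**: two planted classes. *Shared-variation* sites give
  the focal allele to a uniform non-empty proper subset of the covered
  breeds (never focal-specific by construction). *Focal-private* sites
  give every covered breed one common alternative allele. With per-covered-
  breed difference probability 1 (private) and 1/2 (shared), the total
  site rate is calibrated so the realized per-breed pairwise difference
  fraction equals `background_diff_rate` (default 0.005, within the
  observed 0.44–0.61% per-base divergence range) and the focal-specific
  proportion equals `focal_unique_fraction` (default 0.02). The suite
  checks both calibrations against binomial sampling error.
* **Enriched units**: for each (unit, multiplier) the focal-private rate
  is multiplied over the unit's gene bodies. The footprint is the gene
  body (not the ± flank): this keeps the planted signal concentrated in
  the unit's coding and window sites while limiting contamination of the
  mode universe. Note the realized fold against the *mode* universe is
  below the planted multiplier, because planted private sites inflate the
  universe proportion at this genome size — the truth record stores the
  multiplier, and recovery is asserted against inside/outside densities.
* **Coverage masks**: fixed 1 kb windows dropped independently per breed
  at rate 0.03, mirroring alignment-block dropout.
* **Focal-only regions**: composite sequences built to target composition
  (defaults: tandem 0.905, G4 0.232) from a tandem-only block (A/C/T unit
  that cannot form G- or C-runs), a G4 chain with varying loops (not
  periodic), a dual block (tandem array of a `GGG`+loop unit, counted by
  both detectors — needed because the two targets may sum past 1), and
  random filler. Because the composition targets may legitimately sum
  past 1, configuration only requires each target in [0, 1]. The region
  replaces a reserved gene-free interval of the focal chromosome and its
  exact interval is subtracted from every breed's mask — operationally
  identical to a focal-only insertion, without shifting the coordinates of
  everything planted before it. Regions are placed first; genes then avoid
  them, and no difference sites are planted inside them (no breed could
  witness one).
* **Randomness**: one seed; independent numpy child streams per component
  (genome, genes, GO, masks, regions, sites). Identical config + seed give
  byte-identical outputs, which the suite asserts through the CLI.

What passing tests on synthetic panels do **not** show: robustness to
alignment artifacts (misalignment, paralog collapse), indels, assembly
errors correlated between breeds, tree-structured sharing, or real
gene/GO structure. They do show the specificity rules, the statistic, the
annotation arithmetic, and the region machinery are implemented exactly.

## Numerical and problem-size choices

* Binomial tails are exact (no approximation or continuity correction);
  the suite verifies agreement with explicit pmf summation to 1e-12 for
  all n ≤ 12 over a p grid.
* Enrichment power/null simulations use 12-breed, 1 Mb panels over 20
  seeds (~440 unit-tests per null panel); breed count does not enter the
  statistic, and these sizes keep the full suite around a minute of
  simulation while leaving the planted 8× GO category's detection
  comfortably powered and the null false-pass rate bounded by the
  binomial tail itself.
* Ties: the panel allele for effect annotation breaks frequency ties
  alphabetically; result tables break p-value ties by unit id.
* Degenerate inputs: an empty universe (|U| = 0) makes fold undefined —
  unit-level calls raise a degenerate-universe error, and mode runners
  return an empty table with the event logged.

## Known limitations

One transcript per gene (with multiple transcripts, the most severe
effect per gene would be the natural extension); no indel effects; flat GO
(no ancestor closure — a hook point exists at the table level, since any
closure can be applied to the gene→term table before it is passed in);
perfect tandem arrays only; the G4 detector is motif-based, not a
thermodynamic model.
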