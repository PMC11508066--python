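"""Effect annotation of difference sites against gene models.

Each focal-genome difference site is annotated per overlapping gene. The
focal genome carries the derived allele; the panel (ancestral) allele is the
most common allele among the covered comparison breeds that differ from the
focal genome. Coding changes are therefore reported panel -> focal, e.g.
``cgt > ctt`` with amino-acid change ``r > l at 643`` (lowercase, 1-based
protein position) — the published reporting format.

Classes partition the genome relative to a gene: coding (nonsynonymous /
synonymous / stopgain / stoploss), splice-site (first ``splice_window``
intronic bases at an exon junction), intronic, gene +/- 10 kb flank, and
intergenic. Stopgain/stoploss are distinct classes and are NOT counted as
missense by the enrichment stage unless explicitly merged.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import ConsistencyError, CoordinateError
from .genome import Genome
from .models import (
    SEVERITY_ORDER,
    DifferenceSite,
    EffectAnnotation,
    EffectClass,
    GeneModel,
)

DEFAULT_FLANK = 10_000
DEFAULT_SPLICE_WINDOW = 2

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_SEVERITY_RANK = {cls: i for i, cls in enumerate(SEVERITY_ORDER)}


def panel_allele(site: DifferenceSite) -> str:
    """Most common non-focal allele among recorded breeds (ancestral proxy).

    Ties break alphabetically so annotation is deterministic.
    """
    records = [a for a in site.recorded_non_focal().values() if a != site.focal_allele]
    if not records:
        raise ConsistencyError(
            f"site {site.chrom}:{site.pos} has no differing breed record"
        )
    counts = Counter(records)
    return min(counts, key=lambda a: (-counts[a], a))


class GeneIndex:
    """Interval lookups over a set of gene models (one transcript each)."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        flank: int = DEFAULT_FLANK,
        splice_window: int = DEFAULT_SPLICE_WINDOW,
    ):
        if flank < 0:
            raise CoordinateError("flank must be >= 0")
        self.flank = flank
        self.splice_window = splice_window
        self.genes: Dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self._window_trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._splice: Dict[str, frozenset] = {}
        for g in genes:
            # half-open internal coordinates for the tree
            lo = max(1, g.start - flank)
            self._window_trees[g.chrom].addi(lo, g.end + flank + 1, g.gene_id)
            self._splice[g.gene_id] = g.splice_positions(splice_window)

    def window_genes(self, chrom: str, pos: int) -> List[str]:
        tree = self._window_trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))


def assign_to_gene_windows(
    site_or_pos, gene_models, flank: int = DEFAULT_FLANK
) -> List[str]:
    """Gene ids whose [start - flank, end + flank] window contains the position."""
    if isinstance(site_or_pos, DifferenceSite):
        chrom, pos = site_or_pos.chrom, site_or_pos.pos
    else:
        chrom, pos = site_or_pos
    if isinstance(gene_models, GeneIndex):
        index = gene_models
        if index.flank != flank:
            index = GeneIndex(list(index.genes.values()), flank=flank)
    else:
        index = GeneIndex(list(gene_models), flank=flank)
    return index.window_genes(chrom, pos)


@dataclass
class _CdsCache:
    spliced: Dict[str, str]

    def get(self, gene: GeneModel, genome: Genome) -> str:
        if gene.gene_id not in self.spliced:
            self.spliced[gene.gene_id] = gene.spliced_cds(genome)
        return self.spliced[gene.gene_id]


def _coding_annotation(
    site: DifferenceSite, gene: GeneModel, genome: Genome, cache: _CdsCache
) -> EffectAnnotation:
    cds = cache.get(gene, genome)
    idx = gene.cds_index(site.pos)
    assert idx is not None
    codon_i = idx // 3
    within = idx % 3
    alt_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    # transcript-strand bases of the two alleles
    focal_tx = site.focal_allele if gene.strand == "+" else _COMPLEMENT[site.focal_allele]
    panel_tx = panel_allele(site)
    if gene.strand == "-":
        panel_tx = _COMPLEMENT[panel_tx]
    if alt_codon[within] != focal_tx:
        raise ConsistencyError(
            f"focal allele {site.focal_allele} at {site.chrom}:{site.pos} does not "
            f"match genome CDS base {alt_codon[within]} of {gene.gene_id}"
        )
    ref_codon = alt_codon[:within] + panel_tx + alt_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        cls = EffectClass.SYNONYMOUS_SNV
    elif alt_aa == "*":
        cls = EffectClass.STOPGAIN
    elif ref_aa == "*":
        cls = EffectClass.STOPLOSS
    else:
        cls = EffectClass.NONSYNONYMOUS_SNV
    codon_change = f"{ref_codon.lower()} > {alt_codon.lower()}"
    aa_change = f"{ref_aa.lower()} > {alt_aa.lower()} at {codon_i + 1}"
    return EffectAnnotation(site, gene.gene_id, cls, codon_change, aa_change)


def annotate_all(
    site: DifferenceSite, index: GeneIndex, genome: Genome, _cache: _CdsCache | None = None
) -> List[EffectAnnotation]:
    """Annotations of one site against every gene whose window contains it.

    Returns annotations sorted most-severe first; a site outside every
    window yields a single INTERGENIC annotation with no gene.
    """
    if site.chrom not in genome.chrom_lengths:
        raise CoordinateError(f"unknown chromosome {site.chrom!r}")
    cache = _cache if _cache is not None else _CdsCache({})
    out: List[EffectAnnotation] = []
    for gene_id in index.window_genes(site.chrom, site.pos):
        gene = index.genes[gene_id]
        if gene.cds_index(site.pos) is not None:
            out.append(_coding_annotation(site, gene, genome, cache))
        elif site.pos in index._splice[gene_id]:
            out.append(EffectAnnotation(site, gene_id, EffectClass.SPLICE_SITE_VARIANT))
        elif gene.start <= site.pos <= gene.end:
            out.append(EffectAnnotation(site, gene_id, EffectClass.INTRONIC))
        else:
            out.append(EffectAnnotation(site, gene_id, EffectClass.FLANK_10KB))
    if not out:
        return [EffectAnnotation(site, None, EffectClass.INTERGENIC)]
    out.sort(key=lambda a: (_SEVERITY_RANK[a.effect_class], a.gene_id))
    return out


def annotate_effect(
    site: DifferenceSite, gene_models, genome: Genome
) -> EffectAnnotation:
    """Single most-severe annotation of a site (one effect class per site)."""
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(list(gene_models))
    return annotate_all(site, index, genome)[0]


def annotate_sites(
    sites: Iterable[DifferenceSite], index: GeneIndex, genome: Genome
) -> pd.DataFrame:
    """Per-(site, gene) annotation table for the whole site list.

    Sites whose focal allele contradicts the genome are dropped with their
    count reported in the ``attrs['n_dropped_mismatch']`` of the frame.
    """
    cache = _CdsCache({})
    rows = []
    dropped = 0
    for site in sites:
        if genome.base(site.chrom, site.pos) != site.focal_allele:
            dropped += 1
            continue
        for ann in annotate_all(site, index, genome, cache):
            rows.append(
                (
                    site.chrom,
                    site.pos,
                    site.focal_allele,
                    ann.gene_id,
                    ann.effect_class.value,
                    ann.codon_change,
                    ann.aa_change,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "focal_allele",
            "gene_id",
            "effect_class",
            "codon_change",
            "aa_change",
        ],
    )
    df.attrs["n_dropped_mismatch"] = dropped
    return df


def protein_diff_oracle(
    site: DifferenceSite, gene: GeneModel, genome: Genome
) -> Tuple[EffectClass, Optional[int], Optional[str], Optional[str]]:
    """Independent effect call by re-translating the entire panel-allele CDS.

    Substitutes the panel (ancestral) allele into the genome, translates the
    whole mutant CDS, and diffs the two proteins. Returns (class, 1-based
    protein position, panel aa, focal aa); position/aa are None for
    synonymous changes. Used to cross-check the per-codon annotation path.
    """
    idx = gene.cds_index(site.pos)
    if idx is None:
        raise CoordinateError(f"{site.chrom}:{site.pos} not in CDS of {gene.gene_id}")
    focal_cds = gene.spliced_cds(genome)
    base = site.focal_allele if gene.strand == "+" else _COMPLEMENT[site.focal_allele]
    if focal_cds[idx] != base:
        raise ConsistencyError("focal allele does not match genome")
    anc_tx = panel_allele(site)
    if gene.strand == "-":
        anc_tx = _COMPLEMENT[anc_tx]
    panel_cds = focal_cds[:idx] + anc_tx + focal_cds[idx + 1 :]
    focal_prot = str(Seq(focal_cds).translate())
    panel_prot = str(Seq(panel_cds).translate())
    diffs = [i for i, (a, b) in enumerate(zip(panel_prot, focal_prot)) if a != b]
    if not diffs:
        return EffectClass.SYNONYMOUS_SNV, None, None, None
    (i,) = diffs
    a, b = panel_prot[i], focal_prot[i]
    if b == "*":
        cls = EffectClass.STOPGAIN
    elif a == "*":
        cls = EffectClass.STOPLOSS
    else:
        cls = EffectClass.NONSYNONYMOUS_SNV
    return cls, i + 1, a.lower(), b.lower()
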