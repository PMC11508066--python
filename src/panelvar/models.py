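"""Core domain types: gene models, difference sites, coverage masks, calls.

Coordinate conventions
----------------------
Public positions and intervals are 1-based inclusive, matching the variant
notation ``chr2:122881444:G > T`` used for the focal breed. CoverageMask
stores intervals internally 0-based half-open; BED I/O is the natural fit
and conversion happens only at the boundaries.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .errors import ConfigurationError, CoordinateError, GeneModelError
from .genome import Genome, revcomp

#: Sentinel allele meaning "this breed's assembly does not cover the position".
UNCOVERED = "UNCOVERED"

VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A stranded, multi-exon CDS on the focal genome.

    ``exons`` are 1-based inclusive intervals in genomic order (sorted by
    start). The first base of the transcript-order CDS is codon position 1;
    phase is therefore handled by construction. One transcript per gene.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: no exons")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise GeneModelError(f"{self.gene_id}: exon {s}-{e} inverted")
            if s <= prev_end:
                raise GeneModelError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: spliced CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def transcript_exons(self) -> Tuple[Tuple[int, int], ...]:
        """Exons ordered 5'->3' along the transcript."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def spliced_cds(self, genome: Genome) -> str:
        """Strand-corrected spliced CDS sequence (starts at codon 1)."""
        parts = [genome.fetch(self.chrom, s, e) for s, e in self.exons]
        cds = "".join(parts)
        return cds if self.strand == "+" else revcomp(cds)

    def cds_index(self, pos: int) -> Optional[int]:
        """0-based index of genomic ``pos`` within the spliced CDS, or None."""
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= pos <= e:
                    return offset + (pos - s)
                offset += e - s + 1
        else:
            for s, e in reversed(self.exons):
                if s <= pos <= e:
                    return offset + (e - pos)
                offset += e - s + 1
        return None

    def genomic_pos(self, cds_index: int) -> int:
        """Genomic position (1-based) of a 0-based spliced-CDS index."""
        if not 0 <= cds_index < self.cds_length:
            raise CoordinateError(f"{self.gene_id}: CDS index {cds_index} out of range")
        remaining = cds_index
        for s, e in self.transcript_exons():
            length = e - s + 1
            if remaining < length:
                return s + remaining if self.strand == "+" else e - remaining
            remaining -= length
        raise AssertionError("unreachable")

    def splice_positions(self, window: int = 2) -> frozenset:
        """Intronic positions within ``window`` bp of an exon/intron junction."""
        positions = set()
        for i, (s, e) in enumerate(self.exons):
            if i > 0:  # junction into the preceding intron
                positions.update(range(s - window, s))
            if i < len(self.exons) - 1:  # junction into the following intron
                positions.update(range(e + 1, e + 1 + window))
        return frozenset(positions)


def translate_cds(genome: Genome, gene: GeneModel, strip_stop: bool = True) -> str:
    """Standard-genetic-code translation of a gene's spliced CDS.

    The terminal stop (if present) is stripped; an internal stop raises a
    gene-model error because the synthetic builder never produces one.
    """
    protein = str(Seq(gene.spliced_cds(genome)).translate())
    if protein.endswith("*") and strip_stop:
        protein = protein[:-1]
    if "*" in protein:
        raise GeneModelError(f"{gene.gene_id}: internal stop codon in CDS")
    return protein


# ---------------------------------------------------------------------------
# Difference sites and coverage
# ---------------------------------------------------------------------------

@dataclass
class DifferenceSite:
    """One focal-genome position where at least one comparison breed differs.

    ``breed_alleles`` holds the explicit per-breed records. Under the
    pairwise-difference table dialect, a breed absent from the map but
    covered by its mask carries the focal allele (absence means identity);
    the :data:`UNCOVERED` sentinel is equivalent to absence of a record.
    """

    chrom: str
    pos: int  # 1-based
    focal_allele: str
    breed_alleles: Dict[str, str] = field(default_factory=dict)

    def recorded_non_focal(self) -> Dict[str, str]:
        return {
            b: a
            for b, a in self.breed_alleles.items()
            if a != UNCOVERED
        }


class Reason(str, Enum):
    SPECIFIC = "SPECIFIC"
    ALLELE_SHARED = "ALLELE_SHARED"
    INSUFFICIENT_PRESENCE = "INSUFFICIENT_PRESENCE"


@dataclass(frozen=True)
class SpecificityCall:
    site: DifferenceSite
    n_covering: int
    is_focal_specific: bool
    reason: Reason

    def __post_init__(self):
        if self.is_focal_specific and self.reason is not Reason.SPECIFIC:
            raise ConfigurationError("is_focal_specific implies reason SPECIFIC")


class CoverageMasks:
    """Per-breed coverage intervals on focal coordinates.

    Intervals are stored 0-based half-open, sorted and merged per
    (breed, chromosome). Built either from BED files or from the simulator's
    window dropout model.
    """

    def __init__(self, intervals: Mapping[str, Mapping[str, Sequence[Tuple[int, int]]]]):
        self._starts: Dict[str, Dict[str, np.ndarray]] = {}
        self._ends: Dict[str, Dict[str, np.ndarray]] = {}
        for breed, per_chrom in intervals.items():
            self._starts[breed] = {}
            self._ends[breed] = {}
            for chrom, ivs in per_chrom.items():
                merged = merge_intervals(ivs)
                self._starts[breed][chrom] = np.array([s for s, _ in merged], dtype=np.int64)
                self._ends[breed][chrom] = np.array([e for _, e in merged], dtype=np.int64)

    @property
    def breeds(self) -> List[str]:
        return list(self._starts)

    def intervals(self, breed: str, chrom: str) -> List[Tuple[int, int]]:
        starts = self._starts.get(breed, {}).get(chrom)
        if starts is None:
            return []
        return list(zip(starts.tolist(), self._ends[breed][chrom].tolist()))

    def covers(self, breed: str, chrom: str, pos: int) -> bool:
        """Whether ``breed``'s mask covers 1-based ``pos``."""
        if breed not in self._starts:
            raise ConfigurationError(f"no coverage mask for breed {breed!r}")
        starts = self._starts[breed].get(chrom)
        if starts is None or len(starts) == 0:
            return False
        p = pos - 1
        i = bisect.bisect_right(starts, p) - 1
        return i >= 0 and p < self._ends[breed][chrom][i]

    def covering_breeds(self, chrom: str, pos: int) -> List[str]:
        return [b for b in self._starts if self.covers(b, chrom, pos)]

    def presence(self, chrom: str, pos: int) -> int:
        return len(self.covering_breeds(chrom, pos))

    def subtract(self, chrom: str, start0: int, end0: int) -> None:
        """Remove [start0, end0) from every breed's mask (0-based half-open)."""
        for breed in self._starts:
            starts = self._starts[breed].get(chrom)
            if starts is None:
                continue
            ends = self._ends[breed][chrom]
            new: List[Tuple[int, int]] = []
            for s, e in zip(starts.tolist(), ends.tolist()):
                if e <= start0 or s >= end0:
                    new.append((s, e))
                    continue
                if s < start0:
                    new.append((s, start0))
                if e > end0:
                    new.append((end0, e))
            self._starts[breed][chrom] = np.array([s for s, _ in new], dtype=np.int64)
            self._ends[breed][chrom] = np.array([e for _, e in new], dtype=np.int64)

    def union_intervals(self, chrom: str) -> List[Tuple[int, int]]:
        """Union of all breeds' coverage on ``chrom`` (0-based half-open)."""
        ivs: List[Tuple[int, int]] = []
        for breed in self._starts:
            ivs.extend(self.intervals(breed, chrom))
        return merge_intervals(ivs)


def merge_intervals(ivs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Sort and merge 0-based half-open intervals; drops empty ones."""
    out: List[Tuple[int, int]] = []
    for s, e in sorted((s, e) for s, e in ivs if e > s):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Effect annotation
# ---------------------------------------------------------------------------

class EffectClass(str, Enum):
    NONSYNONYMOUS_SNV = "NONSYNONYMOUS_SNV"
    SYNONYMOUS_SNV = "SYNONYMOUS_SNV"
    STOPGAIN = "STOPGAIN"
    STOPLOSS = "STOPLOSS"
    SPLICE_SITE_VARIANT = "SPLICE_SITE_VARIANT"
    INTRONIC = "INTRONIC"
    FLANK_10KB = "FLANK_10KB"
    INTERGENIC = "INTERGENIC"


CODING_CLASSES = frozenset(
    {
        EffectClass.NONSYNONYMOUS_SNV,
        EffectClass.SYNONYMOUS_SNV,
        EffectClass.STOPGAIN,
        EffectClass.STOPLOSS,
    }
)

#: Most severe first; used to pick a single site-level annotation when a
#: position falls in several genes.
SEVERITY_ORDER = (
    EffectClass.STOPGAIN,
    EffectClass.STOPLOSS,
    EffectClass.NONSYNONYMOUS_SNV,
    EffectClass.SYNONYMOUS_SNV,
    EffectClass.SPLICE_SITE_VARIANT,
    EffectClass.INTRONIC,
    EffectClass.FLANK_10KB,
    EffectClass.INTERGENIC,
)


@dataclass(frozen=True)
class EffectAnnotation:
    """Effect of a difference site on (at most) one gene.

    ``codon_change`` is ``"ref>alt"`` in lowercase (panel codon first, focal
    codon second) and ``aa_change`` is ``"x > y at P"`` with lowercase
    single-letter amino acids and the 1-based protein position, matching the
    published table format; both are None for non-coding classes.
    """

    site: DifferenceSite
    gene_id: Optional[str]
    effect_class: EffectClass
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None

    def __post_init__(self):
        coding = self.effect_class in CODING_CLASSES
        if coding != (self.codon_change is not None and self.aa_change is not None):
            raise ConfigurationError(
                "codon_change/aa_change must be present exactly for coding classes"
            )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationUniverse:
    """The universe S of difference positions and its focal-specific subset U."""

    S_size: int
    U_size: int

    def __post_init__(self):
        if not 0 <= self.U_size <= self.S_size:
            raise ConfigurationError("need 0 <= |U| <= |S|")

    @property
    def p(self) -> float:
        """Genome-wide proportion of unique (focal-specific) mutations, |U|/|S|."""
        return self.U_size / self.S_size if self.S_size else 0.0


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested unit: a gene, a GO category, or a genomic region."""

    unit_id: str
    n: int  # |S'|
    k: int  # |U'|
    fold: float
    p_value: float
    passes: bool


@dataclass(frozen=True)
class SpecificRegion:
    """A maximal focal-only interval (covered by zero comparison breeds)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    tandem_fraction: Optional[float] = None
    g4_fraction: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1
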