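"""Classification of focal-breed-specific variants from per-breed difference tables.

The focal genome is compared pairwise against a panel of comparison-breed
genomes. Each pairwise comparison yields a difference table (one record per
position where the two genomes disagree) and a coverage mask (the focal
intervals the comparison assembly aligns to). Under this pairwise dialect,
a breed that covers a position but has no record there carries the focal
allele (absence means identity).

A position enters the analysis universe S when enough breeds cover it
(``min_breeds``, by default panel size - 3, mirroring a 30-of-33 rule).
It is focal-specific — a member of U — when, additionally, no covered
breed carries the focal allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .errors import AlignmentDialectError, ConfigurationError, ConsistencyError
from .models import (
    UNCOVERED,
    VALID_BASES,
    CoverageMasks,
    DifferenceSite,
    Reason,
    SpecificityCall,
)

logger = logging.getLogger(__name__)

Position = Tuple[str, int]


def default_min_breeds(panel_size: int) -> int:
    """Presence threshold: panel size minus 3 (e.g. 30 of 33)."""
    if panel_size < 2:
        raise ConfigurationError("panel must contain at least 2 comparison breeds")
    return max(1, panel_size - 3)


def compute_presence(site: DifferenceSite, masks: CoverageMasks) -> int:
    """Number of panel breeds whose coverage mask contains the site position."""
    return masks.presence(site.chrom, site.pos)


def classify_focal_specific(
    site: DifferenceSite, masks: CoverageMasks, min_breeds: int
) -> SpecificityCall:
    """Apply the presence and uniqueness rules to one difference site.

    SPECIFIC iff presence >= min_breeds and no covered breed carries the
    focal allele; a covered breed without an explicit record counts as
    carrying the focal allele (pairwise-difference dialect), so any such
    breed makes the site ALLELE_SHARED.
    """
    if min_breeds < 1:
        raise ConfigurationError("min_breeds must be >= 1")
    covering = masks.covering_breeds(site.chrom, site.pos)
    n_covering = len(covering)
    if n_covering < min_breeds:
        return SpecificityCall(site, n_covering, False, Reason.INSUFFICIENT_PRESENCE)
    records = site.recorded_non_focal()
    for breed in covering:
        allele = records.get(breed)
        if allele is None or allele == site.focal_allele:
            return SpecificityCall(site, n_covering, False, Reason.ALLELE_SHARED)
    return SpecificityCall(site, n_covering, True, Reason.SPECIFIC)


def classify_sites(
    sites: Iterable[DifferenceSite], masks: CoverageMasks, min_breeds: int
) -> List[SpecificityCall]:
    return [classify_focal_specific(s, masks, min_breeds) for s in sites]


def build_sets(calls: Sequence[SpecificityCall]) -> Tuple[Set[Position], Set[Position]]:
    """S = positions passing presence; U = the focal-specific subset.

    Each genomic position is counted once regardless of how many breeds
    differ there. Duplicate positions with conflicting focal alleles are an
    input-consistency error.
    """
    seen: Dict[Position, str] = {}
    S: Set[Position] = set()
    U: Set[Position] = set()
    for call in calls:
        key = (call.site.chrom, call.site.pos)
        prev = seen.get(key)
        if prev is not None and prev != call.site.focal_allele:
            raise ConsistencyError(
                f"conflicting focal alleles at {key[0]}:{key[1]}: {prev} vs "
                f"{call.site.focal_allele}"
            )
        seen[key] = call.site.focal_allele
        if call.reason is not Reason.INSUFFICIENT_PRESENCE:
            S.add(key)
        if call.is_focal_specific:
            U.add(key)
    return S, U


# ---------------------------------------------------------------------------
# Assembling DifferenceSites from per-breed tables
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    """Filter accounting for the table-merge step (count conservation)."""

    n_records: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_uncovered_record: int = 0
    n_sites: int = 0


def assemble_sites(
    tables: Mapping[str, pd.DataFrame],
    masks: CoverageMasks,
    chrom_lengths: Mapping[str, int] | None = None,
) -> Tuple[List[DifferenceSite], AssemblyStats]:
    """Merge per-breed difference tables into deduplicated DifferenceSites.

    Each table has columns (chrom, pos, focal_allele, breed_allele) and
    optionally ``breed``. Records with non-ACGT alleles are dropped with a
    logged count, as are records at positions the breed's own mask does not
    cover (they cannot be interpreted under the pairwise dialect).
    """
    stats = AssemblyStats()
    merged: Dict[Position, DifferenceSite] = {}
    for breed in sorted(tables):
        df = tables[breed]
        for row in df.itertuples(index=False):
            stats.n_records += 1
            chrom, pos = str(row.chrom), int(row.pos)
            focal, other = str(row.focal_allele).upper(), str(row.breed_allele).upper()
            if chrom_lengths is not None and not (1 <= pos <= chrom_lengths.get(chrom, 0)):
                raise ConsistencyError(f"position {chrom}:{pos} outside chromosome")
            if focal not in VALID_BASES or other not in VALID_BASES:
                stats.n_dropped_ambiguous += 1
                continue
            if not masks.covers(breed, chrom, pos):
                stats.n_dropped_uncovered_record += 1
                continue
            key = (chrom, pos)
            site = merged.get(key)
            if site is None:
                merged[key] = DifferenceSite(chrom, pos, focal, {breed: other})
            else:
                if site.focal_allele != focal:
                    raise ConsistencyError(
                        f"conflicting focal alleles at {chrom}:{pos}: "
                        f"{site.focal_allele} vs {focal}"
                    )
                site.breed_alleles[breed] = other
    stats.n_sites = len(merged)
    if stats.n_dropped_ambiguous:
        logger.info("dropped %d records with ambiguous alleles", stats.n_dropped_ambiguous)
    if stats.n_dropped_uncovered_record:
        logger.info(
            "dropped %d records outside their breed's mask", stats.n_dropped_uncovered_record
        )
    return [merged[k] for k in sorted(merged)], stats


def calls_to_frame(calls: Sequence[SpecificityCall]) -> pd.DataFrame:
    """Tabular view of specificity calls for on-disk reports."""
    return pd.DataFrame(
        {
            "chrom": [c.site.chrom for c in calls],
            "pos": [c.site.pos for c in calls],
            "focal_allele": [c.site.focal_allele for c in calls],
            "n_covering": [c.n_covering for c in calls],
            "is_focal_specific": [c.is_focal_specific for c in calls],
            "reason": [c.reason.value for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# Toy pairwise comparator (stand-in plumbing for a whole-genome aligner)
# ---------------------------------------------------------------------------

def call_differences_toy(
    focal_seq: str, other_seq: str, chrom: str = "chr1", breed: str = "other"
) -> Tuple[pd.DataFrame, List[Tuple[int, int]]]:
    """Position-by-position comparison of two equal-length sequences.

    Returns a difference table plus the breed's coverage intervals (0-based
    half-open): positions with N in either sequence are excluded from both
    the table and the mask.
    """
    if len(focal_seq) != len(other_seq):
        raise AlignmentDialectError(
            f"sequence lengths differ ({len(focal_seq)} vs {len(other_seq)}); "
            "the toy comparator requires one coordinate frame"
        )
    focal_seq, other_seq = focal_seq.upper(), other_seq.upper()
    rows = []
    covered: List[Tuple[int, int]] = []
    for i, (f, o) in enumerate(zip(focal_seq, other_seq)):
        if f not in VALID_BASES or o not in VALID_BASES:
            continue
        if covered and covered[-1][1] == i:
            covered[-1] = (covered[-1][0], i + 1)
        else:
            covered.append((i, i + 1))
        if f != o:
            rows.append((chrom, i + 1, f, breed, o))
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "focal_allele", "breed", "breed_allele"]
    )
    return table, covered
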