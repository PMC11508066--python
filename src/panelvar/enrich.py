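"""Length-bias-free binomial test for excess of focal-specific mutations.

Gene-list enrichment systematically favors long genes, which accumulate
more variants by chance. The statistic used here instead conditions on the
total number of difference positions a unit received: with S the universe
of difference positions, U its focal-specific subset and p = |U|/|S|, a
unit with n = |S'| positions of which k = |U'| are focal-specific is scored
by the exact binomial upper tail

    p_value = P(X >= k),  X ~ Binomial(n, p)

and by the effect size

    fold = (k / n) / p.

A unit is flagged when fold >= fold_min (default 2) and p_value < p_max
(default 1e-3). No multiple-testing correction enters the pass flag; a
Benjamini-Hochberg adjusted column is emitted as extra information only.

Four unit-construction modes are provided: per-gene missense, per-gene
+/-10 kb window, per-GO-category missense, and per-GO-category window; a
fifth computation scores externally supplied genomic regions by their
focal-specific variant density relative to the genomic average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ConsistencyError, DegenerateUniverseError
from .models import EffectClass, EnrichmentResult, GeneModel, MutationUniverse

logger = logging.getLogger(__name__)

Position = Tuple[str, int]


class Mode(str, Enum):
    GENE_MISSENSE = "GENE_MISSENSE"
    GENE_FLANK10K = "GENE_FLANK10K"
    GO_MISSENSE = "GO_MISSENSE"
    GO_FLANK10K = "GO_FLANK10K"


@dataclass(frozen=True)
class Thresholds:
    fold_min: float = 2.0
    p_max: float = 1e-3
    n_min: int = 1
    include_stop_in_missense: bool = False
    #: window modes: count sites anywhere in gene body +/- flank (default),
    #: or in the flanks only
    flank_only: bool = False


def binomial_tail(p: float, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p); 1.0 when k = 0."""
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"p={p} outside [0, 1]")
    if not 0 <= k <= n:
        raise ConfigurationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def fold_change(k: int, n: int, universe: MutationUniverse) -> float:
    """Unit proportion of unique mutations over the universe proportion."""
    if n <= 0:
        raise ConfigurationError("fold change undefined for n = 0")
    if universe.p == 0:
        raise DegenerateUniverseError("universe has no focal-specific sites (p = 0)")
    return (k / n) / universe.p


def test_unit(
    unit_sites: Set[Position],
    unit_unique_sites: Set[Position],
    universe: MutationUniverse,
    thresholds: Thresholds = Thresholds(),
    unit_id: str = "unit",
) -> Optional[EnrichmentResult]:
    """Score one unit; returns None (skipped, logged) for empty units."""
    if not unit_unique_sites <= unit_sites:
        raise ConsistencyError(f"{unit_id}: U' is not a subset of S'")
    n, k = len(unit_sites), len(unit_unique_sites)
    if n == 0:
        logger.info("unit %s skipped: no sites in universe", unit_id)
        return None
    p_value = binomial_tail(universe.p, n, k)
    fold = fold_change(k, n, universe)
    passes = (
        n >= thresholds.n_min
        and fold >= thresholds.fold_min
        and p_value < thresholds.p_max
    )
    return EnrichmentResult(unit_id, n, k, fold, p_value, passes)


# ---------------------------------------------------------------------------
# Mode runners
# ---------------------------------------------------------------------------

def _missense_classes(thresholds: Thresholds) -> Set[str]:
    classes = {EffectClass.NONSYNONYMOUS_SNV.value}
    if thresholds.include_stop_in_missense:
        classes |= {EffectClass.STOPGAIN.value, EffectClass.STOPLOSS.value}
    return classes


def _unit_membership(
    mode: Mode,
    annotations: pd.DataFrame,
    go_table: Optional[pd.DataFrame],
    thresholds: Thresholds,
) -> pd.DataFrame:
    """(chrom, pos, is_focal_specific, unit_id) rows for the given mode."""
    need = {"chrom", "pos", "gene_id", "effect_class", "is_focal_specific"}
    missing = need - set(annotations.columns)
    if missing:
        raise ConfigurationError(f"annotation table lacks columns {sorted(missing)}")
    if mode in (Mode.GENE_MISSENSE, Mode.GO_MISSENSE):
        sel = annotations[annotations["effect_class"].isin(_missense_classes(thresholds))]
    elif thresholds.flank_only:
        sel = annotations[annotations["effect_class"] == EffectClass.FLANK_10KB.value]
    else:
        # any site in a gene's +/- flank window: every per-gene annotation row
        # whose class is gene-bound (everything except INTERGENIC)
        sel = annotations[annotations["effect_class"] != EffectClass.INTERGENIC.value]
    sel = sel[["chrom", "pos", "gene_id", "is_focal_specific"]].dropna(subset=["gene_id"])
    if mode in (Mode.GENE_MISSENSE, Mode.GENE_FLANK10K):
        out = sel.rename(columns={"gene_id": "unit_id"})
    else:
        if go_table is None or go_table.empty:
            raise ConfigurationError("GO modes require a non-empty gene -> GO table")
        out = sel.merge(
            go_table[["gene_id", "go_id"]].drop_duplicates(), on="gene_id", how="inner"
        ).rename(columns={"go_id": "unit_id"})
    return out.drop_duplicates(subset=["chrom", "pos", "unit_id"])


def run_mode(
    mode: Mode,
    annotations: pd.DataFrame,
    go_table: Optional[pd.DataFrame] = None,
    thresholds: Thresholds = Thresholds(),
    universe: Optional[MutationUniverse] = None,
) -> pd.DataFrame:
    """Run the binomial enrichment test for every unit of one mode.

    ``annotations`` is the per-(site, gene) effect table joined with the
    specificity calls (column ``is_focal_specific``); it should already be
    restricted to sites passing presence (the universe S). The universe
    proportion defaults to the mode's own universe — all positions entering
    at least one unit, each counted once — as the method prescribes; pass
    ``universe`` to override.

    Returns one row per unit with n > 0, sorted by p-value, with an
    informational BH-adjusted column.
    """
    mode = Mode(mode)
    membership = _unit_membership(mode, annotations, go_table, thresholds)
    positions = membership.drop_duplicates(subset=["chrom", "pos"])
    if universe is None:
        universe = MutationUniverse(
            S_size=len(positions), U_size=int(positions["is_focal_specific"].sum())
        )
    results: List[EnrichmentResult] = []
    if universe.p == 0:
        # no focal-specific sites in this universe: nothing can be enriched
        logger.info("mode %s: degenerate universe (|U|=0), no tests run", mode.value)
        membership = membership.iloc[0:0]
    for unit_id, grp in membership.groupby("unit_id", sort=True):
        sites = set(zip(grp["chrom"], grp["pos"]))
        unique = set(
            zip(
                grp.loc[grp["is_focal_specific"], "chrom"],
                grp.loc[grp["is_focal_specific"], "pos"],
            )
        )
        res = test_unit(sites, unique, universe, thresholds, unit_id=str(unit_id))
        if res is not None:
            results.append(res)
    df = pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in results],
            "n": [r.n for r in results],
            "k": [r.k for r in results],
            "fold": [r.fold for r in results],
            "p_value": [r.p_value for r in results],
            "passes": [r.passes for r in results],
        }
    )
    if len(df):
        df["p_adjusted_bh"] = stats.false_discovery_control(df["p_value"], method="bh")
        df = df.sort_values(["p_value", "unit_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["p_adjusted_bh"] = pd.Series(dtype=float)
    df.attrs["mode"] = mode.value
    df.attrs["universe"] = (universe.S_size, universe.U_size)
    return df


# ---------------------------------------------------------------------------
# Region density
# ---------------------------------------------------------------------------

def region_density_fold(
    region: Tuple[str, int, int],
    specific_positions: Iterable[Position],
    genome_size_considered: int,
) -> float:
    """Focal-specific density in a region over the genomic average density.

    ``region`` is (chrom, start, end), 1-based inclusive.
    """
    chrom, start, end = region
    if end < start:
        raise ConfigurationError(f"zero-length region {chrom}:{start}-{end}")
    if genome_size_considered <= 0:
        raise ConfigurationError("genome_size_considered must be > 0")
    positions = list(specific_positions)
    total = len(positions)
    if total == 0:
        raise DegenerateUniverseError("no focal-specific positions genome-wide")
    in_region = sum(1 for c, p in positions if c == chrom and start <= p <= end)
    region_len = end - start + 1
    return (in_region / region_len) / (total / genome_size_considered)


def intersect_regions(
    specific_variants: Iterable[Position],
    regions: Sequence[Tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Assign focal-specific variants to every overlapping query region.

    ``regions`` rows are (chrom, start, end, name), 1-based inclusive after
    BED conversion. Returns one row per region with the variant count and
    the overlapping positions; regions may overlap, and a variant on a
    region boundary base is counted.
    """
    variants = sorted(specific_variants)
    rows = []
    for chrom, start, end, name in regions:
        hits = [p for c, p in variants if c == chrom and start <= p <= end]
        rows.append(
            {
                "region": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_specific": len(hits),
                "positions": ",".join(map(str, hits)),
            }
        )
    return pd.DataFrame(
        rows, columns=["region", "chrom", "start", "end", "n_specific", "positions"]
    )


def region_density_table(
    regions: Sequence[Tuple[str, int, int, str]],
    specific_positions: Iterable[Position],
    genome_size_considered: int,
) -> pd.DataFrame:
    """Per-region specific-variant counts and density fold changes."""
    positions = list(specific_positions)
    df = intersect_regions(positions, regions)
    folds = []
    for row in df.itertuples(index=False):
        folds.append(
            region_density_fold(
                (row.chrom, row.start, row.end), positions, genome_size_considered
            )
        )
    df["density_fold"] = folds
    return df.drop(columns=["positions"])
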