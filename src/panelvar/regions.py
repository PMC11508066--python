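"""Detection and content profiling of long focal-only genomic regions.

A focal-only (breed-specific) region is a maximal interval of the focal
genome covered by ZERO comparison breeds' alignment masks. Detected regions
are profiled for two sequence features that dominate such regions in
practice: perfect tandem-repeat arrays and G-quadruplex (G4) motifs.

G4 detection uses the canonical quadruplex motif

    G{3,} N{1,7} G{3,} N{1,7} G{3,} N{1,7} G{3,}

on both strands, where N is any of A/C/G/T (a literal ``N`` base never
matches). The reported quantity is the fraction of bases covered by the
union of ALL motif occurrences — per-base semantics, so two overlapping
occurrences never double-count a base.

Tandem detection reports the fraction of bases inside maximal perfect
tandem arrays with unit length 1..max_unit and total array length
>= max(2 x unit, min_array_length). A trailing partial copy extends the
array (periodicity semantics: s[i] == s[i+u] throughout the array).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoordinateError, PanelvarError
from .genome import Genome, revcomp
from .models import CoverageMasks, SpecificRegion, merge_intervals


@dataclass(frozen=True)
class G4Params:
    min_g_run: int = 3
    max_loop: int = 7


@dataclass(frozen=True)
class TandemParams:
    max_unit: int = 50
    min_array_length: int = 10


# ---------------------------------------------------------------------------
# G-quadruplex motif coverage
# ---------------------------------------------------------------------------

def _g_run_lengths(seq: str) -> np.ndarray:
    """run[i] = length of the maximal G run starting at i (0 if seq[i] != G)."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_g = a == ord("G")
    run = np.zeros(len(a), dtype=np.int64)
    count = 0
    for i in range(len(a) - 1, -1, -1):
        count = count + 1 if is_g[i] else 0
        run[i] = count
    return run


def _g4_cover_one_strand(seq: str, params: G4Params) -> np.ndarray:
    """Boolean per-base coverage of G4 motif occurrences on the given strand.

    For each start position i the maximal end of any occurrence starting at
    i is computed by a memoized parse over (position, runs-remaining); every
    occurrence starting at i is a prefix of [i, maxend(i)), so the union of
    these intervals equals the union of all occurrences.
    """
    n = len(seq)
    cover = np.zeros(n, dtype=bool)
    if n == 0:
        return cover
    grun = _g_run_lengths(seq)
    has_n = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
    # prefix sums of N for O(1) "loop contains N" checks
    n_prefix = np.concatenate([[0], np.cumsum(has_n)])
    gmin, lmax = params.min_g_run, params.max_loop
    memo: Dict[Tuple[int, int], int] = {}

    def maxend(i: int, remaining: int) -> int:
        g = grun[i]
        if g < gmin:
            return -1
        if remaining == 1:
            return i + int(g)
        key = (i, remaining)
        if key in memo:
            return memo[key]
        best = -1
        g = int(g)
        # Consuming more than ~gmin+lmax G's into one run is only useful to
        # jump past the run's end, so enumerate two bands of run lengths:
        # short ones (next run may start inside this G run) and long ones
        # (next run starts after it).
        low_band = range(gmin, min(g, gmin + lmax + gmin) + 1)
        high_band = range(max(gmin, g - lmax + 1), g + 1)
        for r in sorted(set(low_band) | set(high_band)):
            base = i + r
            for loop in range(1, lmax + 1):
                j = base + loop
                if j >= n:
                    break
                if n_prefix[j] - n_prefix[base] > 0:
                    break  # N inside the loop; longer loops include it too
                e = maxend(j, remaining - 1)
                if e > best:
                    best = e
        memo[key] = best
        return best

    for i in range(n):
        if grun[i] >= gmin:
            e = maxend(i, 4)
            if e > i:
                cover[i:e] = True
    return cover


def g4_cover(sequence: str, params: G4Params = G4Params()) -> np.ndarray:
    """Per-base boolean coverage by G4 motifs on either strand."""
    if len(sequence) == 0:
        raise PanelvarError("empty sequence")
    seq = sequence.upper()
    fwd = _g4_cover_one_strand(seq, params)
    rev = _g4_cover_one_strand(revcomp(seq), params)[::-1]
    return fwd | rev


def g4_fraction(sequence: str, params: G4Params = G4Params()) -> float:
    """Fraction of bases covered by G4 motifs (both strands, union)."""
    cover = g4_cover(sequence, params)
    return float(cover.sum()) / len(cover)


# ---------------------------------------------------------------------------
# Perfect tandem-repeat coverage
# ---------------------------------------------------------------------------

def tandem_cover(sequence: str, params: TandemParams = TandemParams()) -> np.ndarray:
    """Per-base boolean coverage by maximal perfect tandem arrays."""
    if len(sequence) == 0:
        raise PanelvarError("empty sequence")
    seq = sequence.upper()
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(a)
    valid = (a == ord("A")) | (a == ord("C")) | (a == ord("G")) | (a == ord("T"))
    cover = np.zeros(n, dtype=bool)
    for u in range(1, min(params.max_unit, n - 1) + 1):
        eq = (a[:-u] == a[u:]) & valid[:-u] & valid[u:]
        if not eq.any():
            continue
        # maximal runs of True in eq
        padded = np.concatenate([[False], eq, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        min_match = max(u, params.min_array_length - u)
        for s, e in zip(starts, ends):
            if e - s >= min_match:
                cover[s : e + u] = True
    return cover


def tandem_fraction(sequence: str, params: TandemParams = TandemParams()) -> float:
    """Fraction of bases inside perfect tandem arrays."""
    cover = tandem_cover(sequence, params)
    return float(cover.sum()) / len(cover)


# ---------------------------------------------------------------------------
# Focal-only region detection and profiling
# ---------------------------------------------------------------------------

def find_specific_regions(
    masks: CoverageMasks,
    chrom_lengths: Dict[str, int],
    min_length: int = 1000,
    breeds: Sequence[str] | None = None,
) -> List[SpecificRegion]:
    """Maximal intervals covered by zero comparison breeds, length >= min_length.

    ``breeds`` defaults to every breed with a mask; declaring a breed that
    has no mask is a configuration error (its coverage is unknown, so
    focal-only status cannot be established).
    """
    if min_length < 1:
        raise ConfigurationError("min_length must be >= 1")
    declared = list(breeds) if breeds is not None else masks.breeds
    missing = [b for b in declared if b not in masks.breeds]
    if missing:
        raise ConfigurationError(f"missing coverage mask for breeds: {missing}")
    regions: List[SpecificRegion] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        covered = merge_intervals(
            iv for b in declared for iv in masks.intervals(b, chrom)
        )
        prev_end = 0
        for s, e in covered + [(length, length)]:
            gap = min(s, length) - prev_end
            if gap >= min_length:
                regions.append(SpecificRegion(chrom, prev_end + 1, min(s, length)))
            prev_end = max(prev_end, e)
    return regions


def profile_regions(
    regions: Sequence[SpecificRegion],
    genome: Genome,
    g4_params: G4Params = G4Params(),
    tandem_params: TandemParams = TandemParams(),
    baseline: bool = True,
) -> pd.DataFrame:
    """Per-region tandem/G4 fractions plus a genome-wide baseline row.

    Returns a table with columns (region, chrom, start, end, length,
    tandem_fraction, g4_fraction); the baseline row has region ``GENOME``
    and is computed over all chromosomes.
    """
    rows = []
    lengths = genome.chrom_lengths
    for r in regions:
        if r.chrom not in lengths or r.end > lengths[r.chrom]:
            raise CoordinateError(f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome")
        seq = genome.fetch(r.chrom, r.start, r.end)
        rows.append(
            {
                "region": f"{r.chrom}:{r.start}-{r.end}",
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "tandem_fraction": tandem_fraction(seq, tandem_params),
                "g4_fraction": g4_fraction(seq, g4_params),
            }
        )
    if baseline:
        total = sum(lengths.values())
        t_cov = 0
        g_cov = 0
        for chrom in genome.chroms():
            seq = genome.sequence(chrom)
            t_cov += int(tandem_cover(seq, tandem_params).sum())
            g_cov += int(g4_cover(seq, g4_params).sum())
        rows.append(
            {
                "region": "GENOME",
                "chrom": "*",
                "start": 1,
                "end": total,
                "length": total,
                "tandem_fraction": t_cov / total,
                "g4_fraction": g_cov / total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "chrom",
            "start",
            "end",
            "length",
            "tandem_fraction",
            "g4_fraction",
        ],
    )


def attach_profiles(
    regions: Sequence[SpecificRegion],
    genome: Genome,
    g4_params: G4Params = G4Params(),
    tandem_params: TandemParams = TandemParams(),
) -> List[SpecificRegion]:
    """Return regions with their measured fractions filled in."""
    out = []
    for r in regions:
        seq = genome.fetch(r.chrom, r.start, r.end)
        out.append(
            SpecificRegion(
                r.chrom,
                r.start,
                r.end,
                tandem_fraction=tandem_fraction(seq, tandem_params),
                g4_fraction=g4_fraction(seq, g4_params),
            )
        )
    return out
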