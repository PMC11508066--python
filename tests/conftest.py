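"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import pytest

from panelvar.genome import Genome, revcomp
from panelvar.models import CoverageMasks, DifferenceSite, GeneModel


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def full_masks(breeds: Sequence[str], chrom_lengths: Dict[str, int]) -> CoverageMasks:
    """Masks covering every chromosome end to end for every breed."""
    return CoverageMasks(
        {b: {c: [(0, L)] for c, L in chrom_lengths.items()} for b in breeds}
    )


def plant_cds(
    background: str,
    chrom: str,
    start: int,
    cds: str,
    strand: str,
    gene_id: str = "geneX",
) -> Tuple[Genome, GeneModel]:
    """Write a single-exon CDS into a background sequence at 1-based start."""
    seq = list(background)
    insert = cds if strand == "+" else revcomp(cds)
    seq[start - 1 : start - 1 + len(insert)] = list(insert)
    genome = Genome({chrom: "".join(seq)})
    gene = GeneModel(gene_id, chrom, strand, ((start, start + len(cds) - 1),))
    return genome, gene


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def binom_tail_oracle(p: float, n: int, k: int) -> float:
    """Upper tail P(X >= k) by explicit pmf summation."""
    return sum(
        math.comb(n, j) * (p**j) * ((1.0 - p) ** (n - j)) for j in range(k, n + 1)
    )


def specificity_oracle(
    tables: Dict[str, pd.DataFrame],
    masks: CoverageMasks,
    min_breeds: int,
) -> Dict[Tuple[str, int], dict]:
    """Brute-force re-scan of all breed tables and masks.

    Loops over every recorded position and every breed, with no shared code
    with the classification path. Returns per-position dicts with presence,
    specificity, and reason.
    """
    records: Dict[Tuple[str, int], Dict[str, str]] = {}
    focal: Dict[Tuple[str, int], str] = {}
    for breed, df in tables.items():
        for _, row in df.iterrows():
            key = (str(row["chrom"]), int(row["pos"]))
            focal[key] = str(row["focal_allele"])
            records.setdefault(key, {})[breed] = str(row["breed_allele"])
    out = {}
    breeds = masks.breeds
    for key in sorted(records):
        chrom, pos = key
        presence = 0
        any_match = False
        for b in breeds:
            if masks.covers(b, chrom, pos):
                presence += 1
                allele = records[key].get(b)
                if allele is None or allele == focal[key]:
                    any_match = True
        if presence < min_breeds:
            reason = "INSUFFICIENT_PRESENCE"
        elif any_match:
            reason = "ALLELE_SHARED"
        else:
            reason = "SPECIFIC"
        out[key] = {
            "presence": presence,
            "specific": reason == "SPECIFIC",
            "reason": reason,
        }
    return out


def tandem_cover_oracle(
    seq: str, max_unit: int = 50, min_array: int = 10
) -> List[bool]:
    """Per-base tandem-array coverage by an explicit per-unit scan."""
    seq = seq.upper()
    n = len(seq)
    cover = [False] * n
    for u in range(1, min(max_unit, n - 1) + 1):
        i = 0
        while i < n - u:
            a, b = seq[i], seq[i + u]
            if a == b and a in "ACGT":
                j = i
                while (
                    j < n - u
                    and seq[j] == seq[j + u]
                    and seq[j] in "ACGT"
                ):
                    j += 1
                # array spans [i, j + u), matched length j - i
                if (j + u) - i >= max(2 * u, min_array) and (j - i) >= u:
                    for x in range(i, j + u):
                        cover[x] = True
                i = j + 1
            else:
                i += 1
    return cover


def _g4_maxend_oracle(seq: str, gmin: int = 3, lmax: int = 7) -> List[int]:
    """maxend[i]: furthest end of any G4 motif occurrence starting at i."""
    n = len(seq)
    grun = [0] * n
    run = 0
    for i in range(n - 1, -1, -1):
        run = run + 1 if seq[i] == "G" else 0
        grun[i] = run
    memo: Dict[Tuple[int, int], int] = {}

    def best(i: int, remaining: int) -> int:
        if i >= n or grun[i] < gmin:
            return -1
        if remaining == 1:
            return i + grun[i]
        key = (i, remaining)
        if key in memo:
            return memo[key]
        out = -1
        for r in range(gmin, grun[i] + 1):  # every run length, no shortcuts
            for l in range(1, lmax + 1):
                j = i + r + l
                if j >= n or "N" in seq[i + r : j]:
                    break
                e = best(j, remaining - 1)
                out = max(out, e)
        memo[key] = out
        return out

    return [best(i, 4) for i in range(n)]


def g4_cover_oracle(seq: str, gmin: int = 3, lmax: int = 7) -> List[bool]:
    """Per-base G4 coverage on both strands by exhaustive parse enumeration."""
    seq = seq.upper()
    n = len(seq)
    cover = [False] * n
    for strand_seq, flip in ((seq, False), (revcomp(seq), True)):
        maxend = _g4_maxend_oracle(strand_seq, gmin, lmax)
        for i, e in enumerate(maxend):
            if e > i:
                for x in range(i, e):
                    cover[n - 1 - x if flip else x] = True
    return cover


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_panel():
    """A small but complete synthetic panel used across modules."""
    from panelvar.synthpanel import PanelConfig, generate_panel

    cfg = PanelConfig(
        n_breeds=8,
        chrom_lengths={"chr1": 40_000, "chr2": 25_000},
        n_genes=14,
        n_go_terms=5,
        n_private_regions=2,
        private_region_length_range=(1000, 1600),
        seed=42,
    )
    return generate_panel(cfg)
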