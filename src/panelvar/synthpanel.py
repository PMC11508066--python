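"""Synthetic multi-breed genome panel with machine-readable ground truth.

The generator emulates the product of pairwise whole-genome alignment of a
focal breed against a panel of comparison breeds descended from a common
ancestor (star topology): a focal genome with multi-exon protein-coding
genes, a gene -> GO table, per-breed difference tables and coverage masks,
and planted focal-only regions rich in tandem repeats and G4 motifs.

Two classes of difference site are planted:

* shared-variation sites — a random non-empty proper subset of the covered
  comparison breeds keeps the focal allele, the rest carry one alternative
  allele; by construction such a site can never be called focal-specific;
* focal-private sites — the focal genome carries a derived allele that no
  comparison breed has; inside each enriched unit (a gene or GO category)
  the private rate is multiplier x the base rate.

Site rates are calibrated so that the realized per-breed pairwise
difference fraction matches ``background_diff_rate`` and the proportion of
difference sites that are focal-private matches ``focal_unique_fraction``.
All randomness flows from one seeded generator; identical config + seed
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import regions as regions_mod
from .effects import GeneIndex, protein_diff_oracle
from .errors import ConfigurationError, GenerationError
from .genome import Genome, revcomp
from .models import CoverageMasks, DifferenceSite, GeneModel

_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

def _default_chroms() -> Dict[str, int]:
    return {"chr1": 500_000, "chr2": 300_000, "chr3": 200_000}


@dataclass
class PanelConfig:
    """Study conditions for one synthetic panel.

    Defaults emulate the real setting at desk scale: 33 comparison breeds,
    ~1 Mb of focal genome, per-base pairwise divergence 0.5% (the observed
    range is 0.44-0.61%), a 2% focal-specific proportion among difference
    sites, and focal-only regions of 1000-4857 bp built to ~90.5% tandem
    repeats and ~23.2% G4 content.
    """

    n_breeds: int = 33
    chrom_lengths: Dict[str, int] = field(default_factory=_default_chroms)
    gc_content: float = 0.42
    n_genes: int = 200
    exons_per_gene: Tuple[int, int] = (2, 6)
    cds_length_range: Tuple[int, int] = (300, 1800)
    intron_length_range: Tuple[int, int] = (60, 400)
    background_diff_rate: float = 0.005
    focal_unique_fraction: float = 0.02
    enriched_units: Tuple[Tuple[str, float], ...] = ()
    n_go_terms: int = 20
    go_terms_per_gene: Tuple[int, int] = (1, 3)
    n_private_regions: int = 8
    private_region_length_range: Tuple[int, int] = (1000, 4857)
    private_region_tandem: float = 0.905
    private_region_g4: float = 0.232
    uncovered_breed_fraction: float = 0.03
    mask_window: int = 1000
    flank: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_breeds < 2:
            raise ConfigurationError("n_breeds must be >= 2")
        for name, length in self.chrom_lengths.items():
            if length < 1:
                raise ConfigurationError(f"chromosome {name!r} length must be >= 1")
        for name in (
            "gc_content",
            "background_diff_rate",
            "focal_unique_fraction",
            "uncovered_breed_fraction",
            "private_region_tandem",
            "private_region_g4",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3:
            raise ConfigurationError("cds_length_range bounds must be multiples of 3")
        if lo < 6:
            raise ConfigurationError("CDS must hold at least start + stop codons")
        for unit, mult in self.enriched_units:
            if mult < 1:
                raise ConfigurationError(f"multiplier for {unit!r} must be >= 1")

    @property
    def breeds(self) -> List[str]:
        return [f"breed{i:02d}" for i in range(1, self.n_breeds + 1)]


@dataclass
class PanelTruth:
    """Ground truth of one generated panel.

    ``focal_specific_sites`` records every planted focal-private site (with
    its ancestral panel allele and, for CDS sites, the effect obtained by
    whole-protein re-translation); ``shared_sites`` the planted
    shared-variation sites; ``unit_multipliers`` the true per-unit rate
    multipliers; ``private_regions`` the planted focal-only intervals with
    target and as-built composition fractions.
    """

    focal_specific_sites: List[dict] = field(default_factory=list)
    shared_sites: List[dict] = field(default_factory=list)
    unit_multipliers: Dict[str, float] = field(default_factory=dict)
    private_regions: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PanelTruth":
        return cls(
            focal_specific_sites=list(d.get("focal_specific_sites", [])),
            shared_sites=list(d.get("shared_sites", [])),
            unit_multipliers=dict(d.get("unit_multipliers", {})),
            private_regions=list(d.get("private_regions", [])),
        )


@dataclass
class PanelBundle:
    """Everything the downstream stages consume, plus the truth record."""

    config: PanelConfig
    genome: Genome
    genes: List[GeneModel]
    go_table: pd.DataFrame
    tables: Dict[str, pd.DataFrame]
    masks: CoverageMasks
    truth: PanelTruth


# ---------------------------------------------------------------------------
# Genome and gene planting
# ---------------------------------------------------------------------------

def generate_genome(
    chrom_lengths: Mapping[str, int], gc_content: float, rng
) -> Genome:
    """I.i.d. random genome with P(G) = P(C) = gc_content / 2."""
    rng = _as_rng(rng)
    if not 0.0 <= gc_content <= 1.0:
        raise ConfigurationError(f"gc_content={gc_content} outside [0, 1]")
    probs = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    seqs = {}
    for name in chrom_lengths:
        length = chrom_lengths[name]
        if length < 1:
            raise ConfigurationError(f"chromosome {name!r} length must be >= 1")
        draws = rng.choice(4, size=length, p=probs)
        seqs[name] = _BASES[draws].tobytes().decode()
    return Genome(seqs)


def _random_cds(n_codons: int, rng) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _split_lengths(total: int, parts: int, rng) -> List[int]:
    """Random composition of ``total`` into ``parts`` positive integers."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def plant_genes(
    genome: Genome,
    config: PanelConfig,
    rng,
    forbidden: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> Tuple[Genome, List[GeneModel]]:
    """Write non-overlapping multi-exon protein-coding genes into the genome.

    Every gene starts with ATG, ends with a stop, has no in-frame internal
    stop, and carries canonical splice dinucleotides in transcript
    orientation; about half the genes land on the minus strand. Genes are
    laid out by randomly partitioning the free space of each chromosome
    segment (segments are the stretches between ``forbidden`` intervals, if
    any), so placement never needs rejection retries; a genome too small
    for the requested genes is a generation error.
    """
    rng = _as_rng(rng)
    margin = 50  # bp kept gene-free on each side
    # free segments per chromosome, 1-based inclusive
    segments: List[Tuple[str, int, int]] = []
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        blocked = sorted(
            (max(1, s), min(L, e)) for c, s, e in (forbidden or []) if c == chrom
        )
        cursor = 1
        for s, e in blocked + [(L + 1, L + 1)]:
            if s > cursor:
                segments.append((chrom, cursor, s - 1))
            cursor = max(cursor, e + 1)
    # per-gene structural plans
    plans = []
    for _ in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        lo, hi = config.cds_length_range
        cds_len = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        exon_lens = _split_lengths(cds_len, n_ex, rng)
        intron_lens = [
            int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
            for _ in range(n_ex - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        plans.append((exon_lens, intron_lens, strand))
    # assign plans to segments proportionally to remaining capacity
    capacity = np.array([e - s + 1 - margin for _, s, e in segments], dtype=float)
    seg_plans: List[List[tuple]] = [[] for _ in segments]
    for plan in plans:
        span = sum(plan[0]) + sum(plan[1])
        room = np.maximum(capacity - span - margin, 0.0)
        if room.sum() == 0:
            raise GenerationError(
                f"cannot place {config.n_genes} genes without overlap"
            )
        si = int(rng.choice(len(segments), p=room / room.sum()))
        seg_plans[si].append(plan)
        capacity[si] -= span + margin
    genes: List[GeneModel] = []
    counter = 0
    order = np.argsort([f"{c}:{s:012d}" for c, s, _ in segments])
    for si in order:
        chrom, seg_start, seg_end = segments[si]
        chosen = seg_plans[si]
        if not chosen:
            continue
        spans = [sum(e) + sum(i) for e, i, _ in chosen]
        free = (seg_end - seg_start + 1) - sum(spans) - margin * (len(chosen) + 1)
        assert free >= 0
        gaps = rng.multinomial(free, np.full(len(chosen) + 1, 1.0 / (len(chosen) + 1)))
        cursor = seg_start - 1
        for plan, gap in zip(chosen, gaps[:-1]):
            cursor += int(gap) + margin
            start = cursor + 1  # 1-based
            exon_lens, intron_lens, strand = plan
            counter += 1
            gene = _write_gene(
                genome, f"gene{counter:04d}", chrom, start, exon_lens, intron_lens, strand, rng
            )
            genes.append(gene)
            cursor += sum(exon_lens) + sum(intron_lens)
        # trailing gap implicit
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genome, genes


def _write_gene(
    genome: Genome,
    gene_id: str,
    chrom: str,
    start: int,
    exon_lens_tx: Sequence[int],
    intron_lens: Sequence[int],
    strand: str,
    rng,
) -> GeneModel:
    cds = _random_cds(sum(exon_lens_tx) // 3, rng)
    # transcript-order chunks
    chunks = []
    off = 0
    for l in exon_lens_tx:
        chunks.append(cds[off : off + l])
        off += l
    # genomic order: for minus strand the first genomic exon is the last
    # transcript exon, reverse-complemented
    if strand == "+":
        genomic_chunks = chunks
        genomic_introns = [_intron_seq(l, rng) for l in intron_lens]
    else:
        genomic_chunks = [revcomp(c) for c in reversed(chunks)]
        genomic_introns = [revcomp(_intron_seq(l, rng)) for l in reversed(list(intron_lens))]
    exons = []
    pos = start
    for j, chunk in enumerate(genomic_chunks):
        exons.append((pos, pos + len(chunk) - 1))
        genome.replace(chrom, pos, chunk)
        pos += len(chunk)
        if j < len(genomic_introns):
            genome.replace(chrom, pos, genomic_introns[j])
            pos += len(genomic_introns[j])
    return GeneModel(gene_id, chrom, strand, tuple(exons))


def _intron_seq(length: int, rng) -> str:
    """Random intron with canonical GT...AG in transcript orientation."""
    body = _BASES[rng.choice(4, size=max(0, length - 4))].tobytes().decode()
    return ("GT" + body + "AG")[:length] if length >= 4 else "GTAG"[:length]


def make_go_table(genes: Sequence[GeneModel], config: PanelConfig, rng) -> pd.DataFrame:
    """Flat gene -> GO assignment table (gene_id, go_id, go_name)."""
    rng = _as_rng(rng)
    if config.n_go_terms < 1:
        return pd.DataFrame(columns=["gene_id", "go_id", "go_name"])
    terms = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    lo, hi = config.go_terms_per_gene
    rows = []
    for gene in genes:
        n_terms = int(rng.integers(lo, hi + 1))
        for ti in sorted(rng.choice(len(terms), size=min(n_terms, len(terms)), replace=False)):
            rows.append((gene.gene_id, terms[ti], f"synthetic category {ti + 1}"))
    return pd.DataFrame(rows, columns=["gene_id", "go_id", "go_name"])


# ---------------------------------------------------------------------------
# Coverage masks
# ---------------------------------------------------------------------------

def generate_masks(genome: Genome, config: PanelConfig, rng) -> CoverageMasks:
    """Per-breed masks: fixed windows dropped independently per breed."""
    rng = _as_rng(rng)
    w = config.mask_window
    intervals: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    lengths = genome.chrom_lengths
    for breed in config.breeds:
        intervals[breed] = {}
        for chrom in sorted(lengths):
            L = lengths[chrom]
            n_windows = (L + w - 1) // w
            keep = rng.random(n_windows) >= config.uncovered_breed_fraction
            ivs = [
                (i * w, min((i + 1) * w, L)) for i in np.flatnonzero(keep)
            ]
            intervals[breed][chrom] = ivs
    return CoverageMasks(intervals)


# ---------------------------------------------------------------------------
# Focal-only regions
# ---------------------------------------------------------------------------

def _tandem_only_block(t_len: int, rng) -> str:
    """Perfect tandem array that cannot register as G4 on either strand.

    The unit avoids G entirely and never forms a C-C dinucleotide across
    copies, so neither G-runs nor C-runs of length >= 3 can arise.
    """
    if t_len <= 0:
        return ""
    while True:
        u = int(rng.integers(3, 13))
        unit = "".join("ACT"[i] for i in rng.choice(3, size=u))
        if len(set(unit)) > 1 and "CC" not in unit * 2:
            break
    reps = -(-t_len // u)
    return (unit * reps)[:t_len]


def _g4_only_block(g_len: int, rng) -> str:
    """Chain of G4 motif instances with varying loops (not a tandem array)."""
    parts: List[str] = []
    total = 0
    while total < g_len:
        loops = [
            "".join("ACT"[i] for i in rng.choice(3, size=int(rng.integers(1, 4))))
            for _ in range(3)
        ]
        inst = "GGG" + loops[0] + "GGG" + loops[1] + "GGG" + loops[2] + "GGG"
        parts.append(inst)
        total += len(inst)
    return "".join(parts)[:g_len]


def _dual_block(d_len: int, rng) -> str:
    """Tandem array whose unit is itself a G4 motif quarter (counts in both)."""
    if d_len <= 0:
        return ""
    loop = "".join("ACT"[i] for i in rng.choice(3, size=2))
    unit = "GGG" + loop  # e.g. GGGTA repeated: perfect array AND G4 chain
    reps = -(-d_len // len(unit))
    return (unit * reps)[:d_len]


def build_region_sequence(
    length: int, tandem_target: float, g4_target: float, rng
) -> str:
    """Composite sequence hitting the requested tandem/G4 composition.

    The two annotations are measured independently, so a base may count in
    both fractions and the targets may sum past 1. When they do, the excess
    is realized as a dual block — a perfect tandem array whose unit is a
    G-run plus short loop, which both detectors cover in full. Layout:
    [tandem-only][filler][dual][G4-only].
    """
    rng = _as_rng(rng)
    if not (0.0 <= tandem_target <= 1.0 and 0.0 <= g4_target <= 1.0):
        raise ConfigurationError("composition targets must each lie in [0, 1]")
    overlap = max(0.0, tandem_target + g4_target - 1.0)
    d_len = int(round(overlap * length))
    t_len = max(0, int(round(tandem_target * length)) - d_len)
    g_len = max(0, int(round(g4_target * length)) - d_len)
    f_len = length - t_len - g_len - d_len
    if f_len < 0:  # rounding overshoot of at most a few bases
        g_len = max(0, g_len + f_len)
        f_len = length - t_len - g_len - d_len
    if f_len < 0:
        t_len = max(0, t_len + f_len)
        f_len = length - t_len - g_len - d_len
    seq = (
        _tandem_only_block(t_len, rng)
        + (_BASES[rng.choice(4, size=f_len)].tobytes().decode() if f_len > 0 else "")
        + _dual_block(d_len, rng)
        + _g4_only_block(g_len, rng)
    )
    assert len(seq) == length
    return seq


def plant_private_regions(
    genome: Genome,
    masks: CoverageMasks,
    config: PanelConfig,
    rng,
    forbidden: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> Tuple[Genome, CoverageMasks, List[dict]]:
    """Realize focal-only regions and hide them from every breed's mask.

    Each region's composite sequence replaces a gene-free stretch of the
    focal genome and the exact interval is subtracted from all masks, which
    is what "absent from the other breeds" means downstream. Returns truth
    records with target and as-built (re-measured) composition fractions.
    """
    rng = _as_rng(rng)
    lo, hi = config.private_region_length_range
    if lo < 1 or hi < lo:
        raise ConfigurationError("invalid private_region_length_range")
    records: List[dict] = []
    chroms = sorted(config.chrom_lengths)
    gene_margin = 100  # bp kept between a region and any gene
    region_margin = 2 * config.mask_window  # keeps regions apart in detection
    # free gaps per chromosome (1-based inclusive), genes + margins excluded
    gaps: List[Tuple[str, int, int]] = []
    for chrom in chroms:
        L = config.chrom_lengths[chrom]
        blocked = sorted(
            (max(1, s - gene_margin), min(L, e + gene_margin))
            for c, s, e in (forbidden or [])
            if c == chrom
        )
        cursor = 1 + region_margin
        for s, e in blocked + [(L - region_margin + 1, L)]:
            if s > cursor:
                gaps.append((chrom, cursor, min(s - 1, L - region_margin)))
            cursor = max(cursor, e + 1)
    for i in range(config.n_private_regions):
        length = int(rng.integers(lo, hi + 1))
        fits = [g for g in gaps if g[2] - g[1] + 1 >= length]
        if not fits:
            raise GenerationError(f"could not place private region {i + 1}")
        weights = np.array([g[2] - g[1] + 2 - length for g in fits], dtype=float)
        gi = int(rng.choice(len(fits), p=weights / weights.sum()))
        chrom, gs, ge = fits[gi]
        start = int(rng.integers(gs, ge - length + 2))
        end = start + length - 1
        # split the gap around the placed region
        gaps.remove(fits[gi])
        if start - region_margin - 1 >= gs:
            gaps.append((chrom, gs, start - region_margin - 1))
        if ge >= end + region_margin + 1:
            gaps.append((chrom, end + region_margin + 1, ge))
        gaps.sort()
        seq = build_region_sequence(
            length, config.private_region_tandem, config.private_region_g4, rng
        )
        genome.replace(chrom, start, seq)
        masks.subtract(chrom, start - 1, end)
        records.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "length": length,
                "target_tandem": config.private_region_tandem,
                "target_g4": config.private_region_g4,
                "tandem_fraction": regions_mod.tandem_fraction(seq),
                "g4_fraction": regions_mod.g4_fraction(seq),
            }
        )
    records.sort(key=lambda r: (r["chrom"], r["start"]))
    return genome, masks, records


# ---------------------------------------------------------------------------
# Difference simulation
# ---------------------------------------------------------------------------

def _enriched_footprints(
    config: PanelConfig,
    genes: Sequence[GeneModel],
    go_table: pd.DataFrame,
) -> Dict[str, List[Tuple[int, int, float]]]:
    """Per-chrom (start, end, multiplier) footprints, 1-based inclusive.

    An enriched unit's footprint is the union of its genes' bodies; the
    focal-private rate is multiplied there, which elevates both the unit's
    coding sites and (through gene-body containment) its window sites.
    """
    by_gene = {g.gene_id: g for g in genes}
    go_members: Dict[str, List[str]] = {}
    if go_table is not None and len(go_table):
        for go_id, grp in go_table.groupby("go_id"):
            go_members[str(go_id)] = sorted(grp["gene_id"].unique())
    out: Dict[str, List[Tuple[int, int, float]]] = {}
    for unit, mult in config.enriched_units:
        if unit in by_gene:
            members = [by_gene[unit]]
        elif unit in go_members:
            members = [by_gene[g] for g in go_members[unit]]
        else:
            raise ConfigurationError(f"enriched unit {unit!r} not found in gene or GO inputs")
        for g in members:
            out.setdefault(g.chrom, []).append((g.start, g.end, float(mult)))
    return out


def simulate_breed_differences(
    genome: Genome,
    genes: Sequence[GeneModel],
    go_table: pd.DataFrame,
    config: PanelConfig,
    rng,
    masks: Optional[CoverageMasks] = None,
    exclude: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> Tuple[Dict[str, pd.DataFrame], CoverageMasks, PanelTruth]:
    """Plant shared-variation and focal-private sites; emit per-breed tables.

    ``exclude`` intervals (1-based inclusive; typically the focal-only
    regions) receive no sites. If ``masks`` is omitted, fresh masks are
    generated from the same stream.
    """
    rng = _as_rng(rng)
    if masks is None:
        masks = generate_masks(genome, config, rng)
    breeds = config.breeds
    B = len(breeds)
    q = config.focal_unique_fraction
    # calibration: per covered breed, a private site always differs and a
    # shared site differs with probability 1/2 (uniform matching subset)
    denom = (1.0 - config.uncovered_breed_fraction) * (q + (1.0 - q) / 2.0)
    t_rate = config.background_diff_rate / denom if denom > 0 else 0.0
    rate_shared = t_rate * (1.0 - q)
    rate_private = t_rate * q
    footprints = _enriched_footprints(config, genes, go_table)
    index0 = GeneIndex(list(genes), flank=0)
    truth = PanelTruth(unit_multipliers=dict(config.enriched_units))
    rows: Dict[str, list] = {b: [] for b in breeds}
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        eligible = np.ones(L, dtype=bool)  # index = pos - 1
        for c, s, e in exclude or []:
            if c == chrom:
                eligible[s - 1 : e] = False
        mult = np.ones(L)
        for s, e, m in footprints.get(chrom, []):
            seg = slice(s - 1, min(e, L))
            mult[seg] = np.maximum(mult[seg], m)
        draws = rng.random(L)
        private_mask = eligible & (draws < rate_private * mult)
        draws2 = rng.random(L)
        shared_mask = eligible & ~private_mask & (draws2 < rate_shared)
        for pos0 in np.flatnonzero(private_mask | shared_mask):
            pos = int(pos0) + 1
            is_private = bool(private_mask[pos0])
            focal = genome.base(chrom, pos)
            if focal not in "ACGT":
                continue
            covered = masks.covering_breeds(chrom, pos)
            alt = _other_base(focal, rng)
            if is_private:
                if not covered:
                    continue  # nothing would witness the site
                for b in covered:
                    rows[b].append((chrom, pos, focal, b, alt))
                rec = {"chrom": chrom, "pos": pos, "allele": focal, "panel_allele": alt}
                rec.update(_truth_effect(chrom, pos, focal, alt, index0, genome))
                truth.focal_specific_sites.append(rec)
            else:
                if len(covered) < 2:
                    continue  # need a matching and a differing breed
                n_match = int(rng.integers(1, len(covered)))
                matching = set(
                    covered[i]
                    for i in rng.choice(len(covered), size=n_match, replace=False)
                )
                for b in covered:
                    if b not in matching:
                        rows[b].append((chrom, pos, focal, b, alt))
                truth.shared_sites.append(
                    {"chrom": chrom, "pos": pos, "allele": focal, "panel_allele": alt}
                )
    tables = {
        b: pd.DataFrame(
            rows[b], columns=["chrom", "pos", "focal_allele", "breed", "breed_allele"]
        )
        for b in breeds
    }
    return tables, masks, truth


def _truth_effect(
    chrom: str, pos: int, focal: str, panel: str, index0: GeneIndex, genome: Genome
) -> dict:
    """Effect of a private CDS site via whole-protein re-translation."""
    for gene_id in index0.window_genes(chrom, pos):
        gene = index0.genes[gene_id]
        if gene.cds_index(pos) is None:
            continue
        site = DifferenceSite(chrom, pos, focal, {"_panel": panel})
        cls, aa_pos, ref_aa, alt_aa = protein_diff_oracle(site, gene, genome)
        return {
            "gene_id": gene_id,
            "effect_class": cls.value,
            "aa_pos": aa_pos,
            "ref_aa": ref_aa,
            "alt_aa": alt_aa,
        }
    return {}


def _other_base(base: str, rng) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def generate_panel(config: PanelConfig) -> PanelBundle:
    """Run the full generator: genome, genes, GO, masks, regions, differences."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]
    genome = generate_genome(config.chrom_lengths, config.gc_content, rngs[0])
    masks = generate_masks(genome, config, rngs[3])
    # regions claim space first; genes then avoid them
    genome, masks, region_records = plant_private_regions(
        genome, masks, config, rngs[4]
    )
    exclude = [(r["chrom"], r["start"], r["end"]) for r in region_records]
    genome, genes = plant_genes(genome, config, rngs[1], forbidden=exclude)
    go_table = make_go_table(genes, config, rngs[2])
    tables, masks, truth = simulate_breed_differences(
        genome, genes, go_table, config, rngs[5], masks=masks, exclude=exclude
    )
    truth.private_regions = region_records
    return PanelBundle(config, genome, genes, go_table, tables, masks, truth)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
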