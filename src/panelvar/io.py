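"""Readers and writers for the standard formats used by the pipeline.

Formats
-------
* FASTA: focal genome, <=80-column wrapped.
* GFF3: gene/mRNA/CDS features, 1-based inclusive; read through gffutils.
* BED: 0-based half-open; coverage masks, detected regions, query regions.
* Difference tables: TSV with header (chrom, pos, focal_allele, breed,
  breed_allele), one file per breed, 1-based positions. Under the pairwise
  dialect, absence of a record at a covered position means the breed
  matches the focal allele.
* GO map: TSV (gene_id, go_id, go_name).
* Truth: JSON, sorted keys.
* VCF: export of the focal-specific set U for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import gffutils
import pandas as pd

from .errors import BedParseError, ConfigurationError
from .models import CoverageMasks, GeneModel, SpecificRegion
from .synthpanel import PanelTruth

DIFF_COLUMNS = ["chrom", "pos", "focal_allele", "breed", "breed_allele"]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs_gene = f"ID={g.gene_id}"
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpanelvar\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{g.chrom}\tpanelvar\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            # phase: bases to skip before the first complete codon of this CDS
            consumed = 0
            exons = g.exons if g.strand == "+" else tuple(reversed(g.exons))
            for s, e in exons:
                phase = (3 - consumed % 3) % 3
                fh.write(
                    f"{g.chrom}\tpanelvar\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )
                consumed += e - s + 1


def read_gff3(path) -> List[GeneModel]:
    """Load one-transcript gene models from a GFF3 file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds: List[Tuple[int, int]] = []
        strand = gene.strand
        for mrna in db.children(gene, featuretype="mRNA"):
            for feat in db.children(mrna, featuretype="CDS"):
                cds.append((feat.start, feat.end))
        if not cds:
            for feat in db.children(gene, featuretype="CDS"):
                cds.append((feat.start, feat.end))
        if not cds:
            continue
        cds.sort()
        genes.append(GeneModel(gene.id, gene.seqid, strand, tuple(cds)))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: Sequence[Tuple[str, int, int]], path, names=None) -> None:
    """Write 0-based half-open intervals, optionally with a name column."""
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(intervals):
            if names is not None:
                fh.write(f"{chrom}\t{s}\t{e}\t{names[i]}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> List[Tuple[str, int, int, str]]:
    """Parse a BED file into (chrom, start0, end0, name) tuples."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError("fewer than 3 columns", ln)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError("non-integer coordinates", ln) from None
            if end < start or start < 0:
                raise BedParseError(f"invalid interval {start}-{end}", ln)
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            out.append((parts[0], start, end, name))
    return out


def write_masks(masks: CoverageMasks, out_dir, chroms: Sequence[str]) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {}
    for breed in masks.breeds:
        path = out_dir / f"mask_{breed}.bed"
        rows = []
        for chrom in chroms:
            rows.extend((chrom, s, e) for s, e in masks.intervals(breed, chrom))
        write_bed(rows, path)
        paths[breed] = path
    return paths


def read_masks(mask_paths: Dict[str, Path]) -> CoverageMasks:
    intervals: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    for breed, path in mask_paths.items():
        per_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e, _ in read_bed(path):
            per_chrom.setdefault(chrom, []).append((s, e))
        intervals[breed] = per_chrom
    return CoverageMasks(intervals)


def regions_to_bed_rows(regions: Sequence[SpecificRegion]) -> List[Tuple[str, int, int]]:
    return [(r.chrom, r.start - 1, r.end) for r in regions]


# ---------------------------------------------------------------------------
# Difference tables and GO map
# ---------------------------------------------------------------------------

def write_difference_tables(tables: Dict[str, pd.DataFrame], out_dir) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {}
    for breed in sorted(tables):
        path = out_dir / f"diff_{breed}.tsv"
        tables[breed].to_csv(path, sep="\t", index=False)
        paths[breed] = path
    return paths


def read_difference_tables(paths: Dict[str, Path]) -> Dict[str, pd.DataFrame]:
    tables = {}
    for breed, path in paths.items():
        df = pd.read_csv(
            path, sep="\t", dtype={"chrom": str, "focal_allele": str, "breed_allele": str}
        )
        missing = set(DIFF_COLUMNS) - {"breed"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
        tables[breed] = df
    return tables


def read_go_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "go_id"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: GO table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Truth JSON and VCF export
# ---------------------------------------------------------------------------

def write_truth(truth: PanelTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> PanelTruth:
    with open(path) as fh:
        return PanelTruth.from_dict(json.load(fh))


def write_specific_vcf(
    calls: pd.DataFrame, chrom_lengths: Dict[str, int], path
) -> None:
    """Minimal VCF of the focal-specific set U (panel allele as REF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelvar\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write(
            '##INFO=<ID=NCOV,Number=1,Type=Integer,Description="Breeds covering the site">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        sel = calls[calls["is_focal_specific"]]
        for row in sel.itertuples(index=False):
            ref = getattr(row, "panel_allele", "N")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{ref}\t{row.focal_allele}\t.\tPASS\t"
                f"NCOV={row.n_covering}\n"
            )
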