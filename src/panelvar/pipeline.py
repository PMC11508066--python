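"""End-to-end analysis: classification -> annotation -> enrichment -> regions.

This is the library face of the ``panelvar analyze`` command; each stage is
also callable on its own. The run report records site counts at every
filter step so that count conservation (sites in = kept + dropped, with
reasons) can be asserted from the log structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from . import effects as effects_mod
from . import enrich as enrich_mod
from . import regions as regions_mod
from . import variants as variants_mod
from .genome import Genome
from .models import CoverageMasks, GeneModel, MutationUniverse
from .errors import ConsistencyError


@dataclass
class AnalysisParams:
    min_breeds: Optional[int] = None  # default: panel size - 3
    flank: int = 10_000
    splice_window: int = 2
    fold_min: float = 2.0
    p_max: float = 1e-3
    min_region_length: int = 1000
    g4_params: regions_mod.G4Params = field(default_factory=regions_mod.G4Params)
    tandem_params: regions_mod.TandemParams = field(default_factory=regions_mod.TandemParams)
    include_stop_in_missense: bool = False
    flank_only: bool = False

    def thresholds(self) -> enrich_mod.Thresholds:
        return enrich_mod.Thresholds(
            fold_min=self.fold_min,
            p_max=self.p_max,
            include_stop_in_missense=self.include_stop_in_missense,
            flank_only=self.flank_only,
        )


@dataclass
class AnalysisResult:
    calls: pd.DataFrame
    S: Set[Tuple[str, int]]
    U: Set[Tuple[str, int]]
    annotations: pd.DataFrame
    enrichment: Dict[str, pd.DataFrame]
    specific_regions: pd.DataFrame
    region_reports: Dict[str, pd.DataFrame]
    report: dict


def analyze(
    genome: Genome,
    genes: Sequence[GeneModel],
    go_table: Optional[pd.DataFrame],
    tables: Mapping[str, pd.DataFrame],
    masks: CoverageMasks,
    params: AnalysisParams = AnalysisParams(),
    query_regions: Optional[Mapping[str, Sequence[Tuple[str, int, int, str]]]] = None,
) -> AnalysisResult:
    """Run the full comparative analysis on one input bundle."""
    chrom_lengths = genome.chrom_lengths
    panel_size = len(masks.breeds)
    min_breeds = (
        params.min_breeds
        if params.min_breeds is not None
        else variants_mod.default_min_breeds(panel_size)
    )

    # 1. classification
    sites, stats = variants_mod.assemble_sites(tables, masks, chrom_lengths)
    calls = variants_mod.classify_sites(sites, masks, min_breeds)
    calls_df = variants_mod.calls_to_frame(calls)
    panel_alleles = []
    for site in sites:
        records = [a for a in site.recorded_non_focal().values() if a != site.focal_allele]
        panel_alleles.append(effects_mod.panel_allele(site) if records else None)
    calls_df["panel_allele"] = panel_alleles
    S, U = variants_mod.build_sets(calls)

    # 2. effect annotation restricted to the universe S
    index = effects_mod.GeneIndex(
        list(genes), flank=params.flank, splice_window=params.splice_window
    )
    s_sites = [s for s in sites if (s.chrom, s.pos) in S]
    ann = effects_mod.annotate_sites(s_sites, index, genome)
    ann["is_focal_specific"] = [
        (c, p) in U for c, p in zip(ann["chrom"], ann["pos"])
    ]

    # 3. enrichment, four unit-construction modes
    thresholds = params.thresholds()
    enrichment: Dict[str, pd.DataFrame] = {}
    for mode in enrich_mod.Mode:
        if mode in (enrich_mod.Mode.GO_MISSENSE, enrich_mod.Mode.GO_FLANK10K) and (
            go_table is None or len(go_table) == 0
        ):
            continue
        enrichment[mode.value] = enrich_mod.run_mode(
            mode, ann, go_table=go_table, thresholds=thresholds
        )

    # 4. focal-only regions + content profile
    found = regions_mod.find_specific_regions(
        masks, chrom_lengths, min_length=params.min_region_length
    )
    profiles = regions_mod.profile_regions(
        found, genome, params.g4_params, params.tandem_params
    )

    # 5. query region overlap / density reports
    genome_size = sum(chrom_lengths.values())
    region_reports: Dict[str, pd.DataFrame] = {}
    for name, bed in (query_regions or {}).items():
        regions_1based = [(c, s + 1, e, n) for c, s, e, n in bed]
        region_reports[name] = enrich_mod.region_density_table(
            regions_1based, U, genome_size
        )

    n_insufficient = int((calls_df["reason"] == "INSUFFICIENT_PRESENCE").sum())
    report = {
        "panel_size": panel_size,
        "min_breeds": min_breeds,
        "filters": {
            "records_in": stats.n_records,
            "records_dropped_ambiguous": stats.n_dropped_ambiguous,
            "records_dropped_uncovered": stats.n_dropped_uncovered_record,
            "sites_merged": stats.n_sites,
            "sites_dropped_insufficient_presence": n_insufficient,
            "sites_in_S": len(S),
            "sites_in_U": len(U),
            "sites_dropped_genome_mismatch": ann.attrs.get("n_dropped_mismatch", 0),
        },
        "universe": {"S": len(S), "U": len(U), "p": (len(U) / len(S)) if S else 0.0},
        "n_specific_regions": len(found),
        "enrichment_passes": {
            mode: int(df["passes"].sum()) for mode, df in enrichment.items()
        },
    }
    if stats.n_sites != len(S) + n_insufficient:
        raise ConsistencyError("site count not conserved across presence filter")
    return AnalysisResult(
        calls=calls_df,
        S=S,
        U=U,
        annotations=ann,
        enrichment=enrichment,
        specific_regions=profiles,
        region_reports=region_reports,
        report=report,
    )


def universe_from_sets(S: Set, U: Set) -> MutationUniverse:
    return MutationUniverse(S_size=len(S), U_size=len(U))
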