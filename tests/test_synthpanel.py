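"""Synthetic panel generator: determinism, construction invariants, calibration."""

import numpy as np
import pandas as pd
import pytest

from panelvar.errors import ConfigurationError
from panelvar.genome import revcomp
from panelvar.models import Reason
from panelvar.synthpanel import (
    PanelConfig,
    build_region_sequence,
    generate_genome,
    generate_panel,
    make_go_table,
    plant_genes,
)
from panelvar.models import translate_cds
from panelvar.variants import assemble_sites, classify_sites, default_min_breeds


class TestGenerateGenome:
    def test_zero_length_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_genome({"chr1": 0}, 0.5, 1)

    def test_gc_one_gives_only_gc(self):
        g = generate_genome({"chr1": 100}, 1.0, 3)
        assert set(g.sequence("chr1")) <= {"G", "C"}

    def test_seed_determinism(self, tmp_path):
        a = generate_genome({"chr1": 500, "chr2": 200}, 0.42, 7)
        b = generate_genome({"chr1": 500, "chr2": 200}, 0.42, 7)
        a.to_fasta(tmp_path / "a.fa")
        b.to_fasta(tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_gc_content_calibrated(self):
        g = generate_genome({"chr1": 200_000}, 0.42, 5)
        seq = g.sequence("chr1")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.42, abs=0.01)


@pytest.fixture(scope="module")
def planted():
    cfg = PanelConfig(
        n_breeds=4,
        chrom_lengths={"chr1": 120_000},
        n_genes=30,
        seed=9,
    )
    genome = generate_genome(cfg.chrom_lengths, cfg.gc_content, 9)
    return plant_genes(genome, cfg, np.random.default_rng(10))


class TestPlantGenes:
    def test_gene_count_conserved(self, planted):
        _, genes = planted
        assert len(genes) == 30

    def test_no_internal_stop_and_starts_with_atg(self, planted):
        genome, genes = planted
        for gene in genes:
            cds = gene.spliced_cds(genome)
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            protein = translate_cds(genome, gene)  # raises on internal stop
            assert len(protein) == gene.n_codons - 1

    def test_minus_strand_genes_present_and_valid(self, planted):
        genome, genes = planted
        minus = [g for g in genes if g.strand == "-"]
        assert 5 <= len(minus) <= 25  # roughly half of 30
        for gene in minus[:5]:
            assert gene.spliced_cds(genome).startswith("ATG")

    def test_exons_disjoint_and_sorted(self, planted):
        _, genes = planted
        for gene in genes:
            for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
                assert e1 < s2

    def test_genes_do_not_overlap(self, planted):
        _, genes = planted
        spans = sorted((g.chrom, g.start, g.end) for g in genes)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 < s2


class TestGoTable:
    def test_every_gene_has_assigned_terms(self):
        cfg = PanelConfig(
            n_breeds=4, chrom_lengths={"chr1": 60_000}, n_genes=10, n_go_terms=6, seed=2
        )
        genome = generate_genome(cfg.chrom_lengths, cfg.gc_content, 2)
        _, genes = plant_genes(genome, cfg, np.random.default_rng(3))
        go = make_go_table(genes, cfg, np.random.default_rng(4))
        lo, hi = cfg.go_terms_per_gene
        counts = go.groupby("gene_id").size()
        assert set(counts.index) == {g.gene_id for g in genes}
        assert counts.between(lo, hi).all()


@pytest.fixture(scope="module")
def bundle():
    cfg = PanelConfig(
        n_breeds=10,
        chrom_lengths={"chr1": 150_000},
        n_genes=25,
        n_go_terms=6,
        n_private_regions=0,
        seed=21,
    )
    return generate_panel(cfg)


class TestDifferenceSimulation:
    def test_pairwise_rate_calibrated_within_three_sd(self, bundle):
        """Realized per-breed difference fraction tracks background_diff_rate."""
        d = bundle.config.background_diff_rate
        L = sum(bundle.config.chrom_lengths.values())
        sd = np.sqrt(d * (1 - d) / L)
        rates = [len(df) / L for df in bundle.tables.values()]
        assert abs(np.mean(rates) - d) < 3 * sd

    def test_focal_specific_fraction_near_config(self, bundle):
        n_priv = len(bundle.truth.focal_specific_sites)
        n_all = n_priv + len(bundle.truth.shared_sites)
        q = bundle.config.focal_unique_fraction
        sd = np.sqrt(q * (1 - q) / n_all)
        assert abs(n_priv / n_all - q) < 4 * sd

    def test_truth_sites_all_emitted(self, bundle):
        emitted = set()
        for df in bundle.tables.values():
            emitted.update(zip(df["chrom"], df["pos"]))
        for rec in bundle.truth.focal_specific_sites:
            assert (rec["chrom"], rec["pos"]) in emitted

    def test_truth_and_classification_agree_exactly(self, bundle):
        """Focal-private truth = U when coverage permits; shared never in U."""
        min_breeds = default_min_breeds(bundle.config.n_breeds)
        sites, _ = assemble_sites(bundle.tables, bundle.masks)
        calls = classify_sites(sites, bundle.masks, min_breeds)
        by_pos = {(c.site.chrom, c.site.pos): c for c in calls}
        for rec in bundle.truth.focal_specific_sites:
            call = by_pos[(rec["chrom"], rec["pos"])]
            if call.n_covering >= min_breeds:
                assert call.is_focal_specific
            else:
                assert call.reason is Reason.INSUFFICIENT_PRESENCE
        for rec in bundle.truth.shared_sites:
            call = by_pos.get((rec["chrom"], rec["pos"]))
            if call is not None:
                assert not call.is_focal_specific

    def test_no_enriched_units_means_no_multipliers(self, bundle):
        assert bundle.truth.unit_multipliers == {}

    def test_unknown_enriched_unit_rejected(self):
        cfg = PanelConfig(
            n_breeds=4,
            chrom_lengths={"chr1": 60_000},
            n_genes=5,
            enriched_units=(("no-such-unit", 4.0),),
            seed=1,
        )
        with pytest.raises(ConfigurationError):
            generate_panel(cfg)

    def test_multiplier_recovered_inside_enriched_gene(self):
        """Private-site density in the enriched footprint ~ m x outside density."""
        m = 8.0
        cfg = PanelConfig(
            n_breeds=6,
            chrom_lengths={"chr1": 400_000},
            n_genes=40,
            n_go_terms=8,
            n_private_regions=0,
            enriched_units=(("gene0001", m), ("gene0002", m)),
            background_diff_rate=0.01,
            focal_unique_fraction=0.05,
            seed=33,
        )
        bundle = generate_panel(cfg)
        genes = {g.gene_id: g for g in bundle.genes}
        raw = []
        for gid in ("gene0001", "gene0002"):
            g = genes[gid]
            raw.append((g.start, g.end))  # footprint = gene body
        footprint = []
        for s, e in sorted(raw):  # merge overlapping windows
            if footprint and s <= footprint[-1][1] + 1:
                footprint[-1] = (footprint[-1][0], max(footprint[-1][1], e))
            else:
                footprint.append((s, e))
        fp_len = sum(e - s + 1 for s, e in footprint)
        out_len = 400_000 - fp_len
        inside = outside = 0
        for rec in bundle.truth.focal_specific_sites:
            if any(s <= rec["pos"] <= e for s, e in footprint):
                inside += 1
            else:
                outside += 1
        rate_in = inside / fp_len
        rate_out = outside / out_len
        ratio = rate_in / rate_out
        # binomial sampling error on the planted counts
        se = ratio * np.sqrt(1 / max(inside, 1) + 1 / max(outside, 1))
        assert abs(ratio - m) < 3 * se


class TestRegionBuilder:
    def test_pure_tandem_target(self):
        from panelvar.regions import tandem_fraction

        seq = build_region_sequence(1200, 1.0, 0.0, np.random.default_rng(1))
        assert tandem_fraction(seq) == 1.0

    def test_invalid_targets_rejected(self):
        with pytest.raises(ConfigurationError):
            build_region_sequence(1000, 1.2, 0.0, np.random.default_rng(1))

    def test_regions_uncovered_by_every_breed(self, small_panel):
        for rec in small_panel.truth.private_regions:
            for breed in small_panel.masks.breeds:
                for pos in (rec["start"], (rec["start"] + rec["end"]) // 2, rec["end"]):
                    assert not small_panel.masks.covers(breed, rec["chrom"], pos)


class TestDeterminism:
    def test_identical_config_and_seed_identical_outputs(self):
        cfg = dict(
            n_breeds=5,
            chrom_lengths={"chr1": 30_000},
            n_genes=8,
            n_private_regions=1,
            private_region_length_range=(1000, 1200),
            seed=13,
        )
        b1 = generate_panel(PanelConfig(**cfg))
        b2 = generate_panel(PanelConfig(**cfg))
        assert b1.genome.sequence("chr1") == b2.genome.sequence("chr1")
        assert [g.exons for g in b1.genes] == [g.exons for g in b2.genes]
        for breed in b1.tables:
            pd.testing.assert_frame_equal(b1.tables[breed], b2.tables[breed])
        assert b1.truth.to_dict() == b2.truth.to_dict()
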