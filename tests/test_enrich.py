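"""Binomial tail statistic, fold change, mode runners, region density."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import binom_tail_oracle

from panelvar.enrich import (
    Mode,
    Thresholds,
    binomial_tail,
    fold_change,
    intersect_regions,
    region_density_fold,
    region_density_table,
    run_mode,
)
from panelvar.enrich import test_unit as score_unit
from panelvar.errors import (
    ConfigurationError,
    ConsistencyError,
    DegenerateUniverseError,
)
from panelvar.models import MutationUniverse


class TestBinomialTail:
    def test_whole_sample_space_at_k_zero(self):
        assert binomial_tail(0.3, 17, 0) == 1.0
        assert binomial_tail(0.0, 5, 0) == 1.0

    def test_single_trial(self):
        assert binomial_tail(0.5, 1, 1) == pytest.approx(0.5, abs=1e-15)

    def test_against_pmf_summation(self):
        # frozen from the summation oracle: P(X>=3), X~Bin(10, 0.1)
        expected = binom_tail_oracle(0.1, 10, 3)
        assert expected == pytest.approx(0.0701908258, abs=1e-9)
        assert binomial_tail(0.1, 10, 3) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            binomial_tail(1.2, 5, 2)
        with pytest.raises(ConfigurationError):
            binomial_tail(0.5, 5, 6)

    @settings(derandomize=True, max_examples=60)
    @given(
        n=st.integers(1, 40),
        k=st.integers(0, 40),
        p=st.floats(0.01, 0.99),
    )
    def test_monotonicity_and_sum_rule(self, n, k, p):
        k = min(k, n)
        tail = binomial_tail(p, n, k)
        assert 0.0 < tail <= 1.0
        if k > 0:
            # non-increasing in k; complements sum to 1
            assert tail <= binomial_tail(p, n, k - 1) + 1e-12
            lower = 1.0 - binom_tail_oracle(p, n, k)
            assert tail + lower == pytest.approx(1.0, abs=1e-9)
        assert binomial_tail(min(p + 0.2, 1.0), n, k) >= tail - 1e-12


class TestFoldChange:
    def test_identity_and_arithmetic(self):
        uni = MutationUniverse(1000, 100)
        assert fold_change(10, 100, uni) == pytest.approx(1.0)
        assert fold_change(2, 10, uni) == pytest.approx(2.0)

    def test_degenerate_universe(self):
        with pytest.raises(DegenerateUniverseError):
            fold_change(1, 10, MutationUniverse(100, 0))
        with pytest.raises(ConfigurationError):
            fold_change(0, 0, MutationUniverse(100, 10))


class TestTestUnit:
    UNI = MutationUniverse(1000, 100)

    def test_empty_unit_skipped(self):
        assert score_unit(set(), set(), self.UNI) is None

    def test_k_zero_never_passes(self):
        sites = {("chr1", i) for i in range(1, 21)}
        res = score_unit(sites, set(), self.UNI)
        assert res.p_value == 1.0 and not res.passes and res.fold == 0.0

    def test_subset_violation_rejected(self):
        with pytest.raises(ConsistencyError):
            score_unit({("chr1", 1)}, {("chr1", 2)}, self.UNI)

    def test_hand_computed_result(self):
        sites = {("chr1", i) for i in range(1, 11)}
        unique = {("chr1", i) for i in range(1, 4)}
        res = score_unit(sites, unique, self.UNI, Thresholds())
        assert (res.n, res.k) == (10, 3)
        assert res.fold == pytest.approx(3.0)
        assert res.p_value == pytest.approx(binom_tail_oracle(0.1, 10, 3), abs=1e-12)
        assert not res.passes  # fold 3 >= 2 but p ~ 0.07 >= 1e-3


def _annotation_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "gene_id", "effect_class", "is_focal_specific"]
    )


class TestRunMode:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            run_mode("BOGUS", _annotation_frame([]))

    def test_go_mode_requires_go_table(self):
        ann = _annotation_frame([("chr1", 5, "g1", "NONSYNONYMOUS_SNV", True)])
        with pytest.raises(ConfigurationError):
            run_mode(Mode.GO_MISSENSE, ann, go_table=pd.DataFrame())

    def test_gene_absent_from_go_table_excluded_from_go_universe(self):
        ann = _annotation_frame(
            [
                ("chr1", 5, "g1", "NONSYNONYMOUS_SNV", True),
                ("chr1", 9, "g2", "NONSYNONYMOUS_SNV", False),
                ("chr1", 13, "g2", "NONSYNONYMOUS_SNV", True),
            ]
        )
        go = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:1"], "go_name": ["x"]})
        df = run_mode(Mode.GO_MISSENSE, ann, go_table=go)
        assert df.attrs["universe"] == (1, 1)  # only g1's site
        assert list(df["unit_id"]) == ["GO:1"]

    def test_position_in_two_genes_counts_once_in_universe(self):
        ann = _annotation_frame(
            [
                ("chr1", 5, "g1", "NONSYNONYMOUS_SNV", True),
                ("chr1", 5, "g2", "NONSYNONYMOUS_SNV", True),
                ("chr1", 9, "g1", "NONSYNONYMOUS_SNV", False),
            ]
        )
        df = run_mode(Mode.GENE_MISSENSE, ann)
        assert df.attrs["universe"] == (2, 1)  # position 5 counted once
        by_unit = df.set_index("unit_id")
        assert by_unit.loc["g1", "n"] == 2 and by_unit.loc["g2", "n"] == 1

    def test_stop_classes_excluded_from_missense_by_default(self):
        ann = _annotation_frame(
            [
                ("chr1", 5, "g1", "STOPGAIN", True),
                ("chr1", 9, "g1", "NONSYNONYMOUS_SNV", True),
                ("chr1", 13, "g1", "NONSYNONYMOUS_SNV", False),
            ]
        )
        df = run_mode(Mode.GENE_MISSENSE, ann)
        assert df.attrs["universe"] == (2, 1)
        merged = run_mode(
            Mode.GENE_MISSENSE, ann, thresholds=Thresholds(include_stop_in_missense=True)
        )
        assert merged.attrs["universe"] == (3, 2)

    def test_results_sorted_by_p_value(self, small_panel):
        from panelvar.pipeline import analyze

        res = analyze(
            small_panel.genome,
            small_panel.genes,
            small_panel.go_table,
            small_panel.tables,
            small_panel.masks,
        )
        for df in res.enrichment.values():
            assert list(df["p_value"]) == sorted(df["p_value"])


class TestRegionDensity:
    POSITIONS = [("chr1", p) for p in (100, 200, 300, 400, 1950, 2500, 5000, 7500, 9000, 9999)]

    def test_no_specific_positions_in_region(self):
        assert region_density_fold(("chr1", 8000, 8999), self.POSITIONS, 10_000) == 0.0

    def test_arithmetic_example(self):
        # 10 kb genome, 10 specific positions; 1 kb region holding 4 -> fold 4
        fold = region_density_fold(("chr1", 1, 1000), self.POSITIONS, 10_000)
        assert fold == pytest.approx(4.0)

    def test_random_placement_null_mean_fold_near_one(self):
        rng = np.random.default_rng(7)
        genome_size = 100_000
        positions = [("chr1", int(p)) for p in rng.choice(genome_size, 500, replace=False) + 1]
        folds = []
        for _ in range(400):
            start = int(rng.integers(1, genome_size - 2000))
            folds.append(
                region_density_fold(("chr1", start, start + 1999), positions, genome_size)
            )
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)

    def test_intersect_matches_brute_force(self):
        rng = np.random.default_rng(11)
        variants = [("chr1", int(p)) for p in sorted(rng.choice(5000, 80, replace=False) + 1)]
        regions = []
        for i in range(15):
            s = int(rng.integers(1, 4500))
            regions.append(("chr1", s, s + int(rng.integers(50, 500)), f"r{i}"))
        df = intersect_regions(variants, regions)
        for row, (chrom, s, e, name) in zip(df.itertuples(index=False), regions):
            expected = sum(1 for c, p in variants if c == chrom and s <= p <= e)
            assert row.n_specific == expected

    def test_boundary_base_counted(self):
        df = intersect_regions([("chr1", 100), ("chr1", 200)], [("chr1", 100, 200, "r")])
        assert df.iloc[0].n_specific == 2

    def test_empty_bed_empty_output(self):
        assert intersect_regions([("chr1", 5)], []).empty

    def test_density_table(self):
        df = region_density_table(
            [("chr1", 1, 1000, "a"), ("chr1", 8000, 8999, "b")], self.POSITIONS, 10_000
        )
        assert list(df["density_fold"]) == pytest.approx([4.0, 0.0])

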