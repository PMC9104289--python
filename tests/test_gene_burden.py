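"""Gene/panel burden: regions, assignment, Fisher vs enumeration, FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortvar import gene_burden as gb
from cohortvar import synthetic_data as sd
from cohortvar.models import GeneModel, Panel

from conftest import make_site


def fisher_brute_force(a, b, c, d):
    """Independent oracle: enumerate every table with the observed margins
    and sum hypergeometric probabilities <= that of the observed table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):  # P(upper-left cell == x) under fixed margins
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )
    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestGeneRegion:
    def test_flank_extension(self):
        g = GeneModel(gene_id="G", chrom="chr1", cds_start=100_000, cds_end=120_000)
        r = gb.gene_region(g)
        assert (r.start, r.end) == (95_000, 125_000)

    def test_clipped_at_one(self):
        g = GeneModel(gene_id="G", chrom="chr1", cds_start=3000, cds_end=4000)
        assert gb.gene_region(g, flank=5000).start == 1

    def test_zero_flank_is_cds(self):
        g = GeneModel(gene_id="G", chrom="chr1", cds_start=3000, cds_end=4000)
        r = gb.gene_region(g, flank=0)
        assert (r.start, r.end) == (3000, 4000)


class TestAssignVariants:
    def test_inclusive_boundaries_and_overlap(self):
        regions = [
            gb.GeneRegion("G1", "chr1", 95_000, 125_000),
            gb.GeneRegion("G2", "chr1", 120_000, 180_000),
        ]
        sites = [
            make_site(pos=95_000),
            make_site(pos=94_999),
            make_site(pos=121_000),  # in both regions
        ]
        asg = gb.assign_variants(sites, regions)
        assert [s.pos for s in asg["G1"]] == [95_000, 121_000]
        assert [s.pos for s in asg["G2"]] == [121_000]


def test_variant_scope_filter_impacts():
    sites = [
        make_site(pos=1, impact="LOW", clnsig="Pathogenic"),
        make_site(pos=2, impact="MODIFIER", clnsig="Pathogenic"),
        make_site(pos=3, impact="HIGH", clnsig="Benign"),
        make_site(pos=4, impact="HIGH", clnsig="Likely_pathogenic"),
    ]
    assert [s.pos for s in gb.variant_scope_filter(sites)] == [2, 4]


class TestCumulativeCounts:
    def test_genotype_cohort_sums(self):
        sites = [
            make_site(pos=1, ac=3, carriers=3, cohort_size=1076),
            make_site(pos=2, ac=2, carriers=2, cohort_size=1076),
        ]
        ac, an = gb.cumulative_counts(sites, "a")
        assert (ac, an) == (5, 2152)
        assert round(100 * ac / an, 2) == 0.23

    def test_hom_alt_singleton_contributes_two_alleles(self):
        sites = [make_site(ac=2, carriers=1, cohort_size=1076)]
        assert gb.cumulative_counts(sites, "a")[0] == 2

    def test_frequency_only_uses_median_an(self):
        sites = [
            make_site(pos=1, ac=1, an=30_000, carriers=None),
            make_site(pos=2, ac=1, an=31_000, carriers=None),
            make_site(pos=3, ac=1, an=35_000, carriers=None),
        ]
        for s in sites:
            s.counts["a"].carriers = None
        ac, an = gb.cumulative_counts(sites, "a")
        assert (ac, an) == (3, 31_000)

    def test_empty_site_list(self):
        assert gb.cumulative_counts([], "a", declared_cohort_size=100) == (0, 200)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 1, 1, 1), 1.0),
            ((2, 0, 0, 2), pytest.approx(1 / 3)),
        ],
    )
    def test_hand_cases(self, table, expected):
        assert gb.fisher_exact_2x2(*table) == expected

    def test_cohort_scale_table_matches_enumeration(self):
        a, b, c, d = 5, 2147, 4, 6996
        assert gb.fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_brute_force(a, b, c, d), rel=1e-9
        )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            gb.fisher_exact_2x2(-1, 1, 1, 1)

    @settings(max_examples=150)
    @given(
        a=st.integers(0, 50), b=st.integers(0, 50),
        c=st.integers(0, 50), d=st.integers(0, 50),
    )
    def test_matches_enumeration_small_tables(self, a, b, c, d):
        assert gb.fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_brute_force(a, b, c, d), rel=1e-7, abs=1e-12
        )

    @settings(max_examples=50)
    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    def test_transpose_and_row_swap_invariance(self, a, b, c, d):
        p = gb.fisher_exact_2x2(a, b, c, d)
        assert gb.fisher_exact_2x2(a, c, b, d) == pytest.approx(p)  # transpose
        assert gb.fisher_exact_2x2(c, d, a, b) == pytest.approx(p)  # row swap


class TestBhFdr:
    def test_single_p(self):
        assert gb.bh_fdr([0.04]) == pytest.approx([0.04])

    def test_hand_step_up(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 then cumulative minimum from the top
        assert gb.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert gb.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @settings(max_examples=50)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_at_least_p_and_monotone(self, ps):
        q = gb.bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(max_examples=30)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_reapplication_never_shrinks(self, ps):
        q1 = gb.bh_fdr(ps)
        q2 = gb.bh_fdr(q1)
        assert (q2 >= q1 - 1e-12).all()


class TestCoverageExclusion:
    @pytest.mark.parametrize(
        "frac,retained", [(0.15, False), (0.10, True), (0.0, True)]
    )
    def test_strict_boundary(self, frac, retained):
        g = GeneModel(gene_id="G", chrom="chr1", cds_start=1, cds_end=100)
        kept = gb.exclude_low_coverage_genes([g], {"G": frac})
        assert (len(kept) == 1) is retained

    def test_missing_coverage_retained_with_warning(self):
        g = GeneModel(gene_id="G", chrom="chr1", cds_start=1, cds_end=100)
        with pytest.warns(UserWarning, match="retained"):
            assert gb.exclude_low_coverage_genes([g], {"other": 0.5}) == [g]


class TestRunGeneBurden:
    def test_self_comparison_gives_p_one(self):
        cfg = sd.SimulationConfig(seed=5, n_genes=8, n_b=1076)
        sim = sd.simulate_small_variant_cohorts(cfg)
        # compare cohort A against an identically-counted copy of itself
        sites_b = []
        for s in sim.sites_a:
            t = make_site(
                pos=s.pos, ac=s.cohort("a").ac, an=s.cohort("a").an,
                carriers=None, cohort="b", impact=s.impact, clnsig=s.clnsig,
                clnrevstat=s.clnrevstat, gene=s.gene_ids[0],
            )
            t.counts["b"].carriers = None
            sites_b.append(t)
        out = gb.run_gene_burden(
            sim.sites_a, sites_b, sim.genes,
            declared_size_a=cfg.n_a, declared_size_b=cfg.n_a,
        )
        assert len(out.results)
        assert (out.results["p"] == 1.0).all()

    def test_planted_gene_ranks_first(self):
        cfg = sd.SimulationConfig(
            seed=6, n_genes=20, enriched={4: (0.025, 0.0075)}
        )
        sim = sd.simulate_small_variant_cohorts(cfg)
        out = gb.run_gene_burden(
            sim.sites_a, sim.sites_b, sim.genes,
            declared_size_a=cfg.n_a, declared_size_b=cfg.n_b,
        )
        assert out.results.iloc[0]["unit_id"] == "GENE004"
        assert out.results.iloc[0]["q"] < 0.05

    def test_empty_gene_list(self):
        out = gb.run_gene_burden([], [], [])
        assert out.results.empty

    def test_untouched_genes_not_tested(self):
        cfg = sd.SimulationConfig(seed=7, n_genes=5, n_b=2000)
        sim = sd.simulate_small_variant_cohorts(cfg)
        extra = GeneModel(
            gene_id="EMPTY", chrom="chr2", cds_start=1000, cds_end=2000
        )
        out = gb.run_gene_burden(
            sim.sites_a, sim.sites_b, list(sim.genes) + [extra],
            declared_size_a=cfg.n_a, declared_size_b=cfg.n_b,
        )
        assert "EMPTY" not in set(out.results["unit_id"])


class TestRunPanelBurden:
    @pytest.fixture
    def gene_output(self):
        cfg = sd.SimulationConfig(seed=8, n_genes=10, n_b=4000,
                                  enriched={0: (0.03, 0.005)})
        sim = sd.simulate_small_variant_cohorts(cfg)
        return cfg, gb.run_gene_burden(
            sim.sites_a, sim.sites_b, sim.genes,
            declared_size_a=cfg.n_a, declared_size_b=cfg.n_b,
        )

    def test_single_gene_panel_p_equals_gene_p(self, gene_output):
        cfg, out = gene_output
        panel = Panel(panel_id="P1", name="one", gene_ids=["GENE000"])
        df = gb.run_panel_burden([panel], out)
        gene_p = out.results.set_index("unit_id").loc["GENE000", "p"]
        row = df.iloc[0]
        assert row["p_gene_corrected"] == pytest.approx(row["p"])
        # same sites, same denominators -> same table as the gene test
        assert row["p"] == pytest.approx(gene_p)

    def test_gene_count_correction_capped(self, gene_output):
        _, out = gene_output
        panel = Panel(
            panel_id="P2", name="ten",
            gene_ids=[f"GENE{i:03d}" for i in range(10)],
        )
        df = gb.run_panel_burden([panel], out)
        row = df.iloc[0]
        assert row["p_gene_corrected"] == pytest.approx(min(1.0, row["p"] * 10))

    def test_shared_site_counted_once(self):
        """A site assigned to two panel genes contributes its ac once."""
        site = make_site(pos=50, ac=4, carriers=4, cohort_size=100, an=200,
                         clnsig="Pathogenic", impact="HIGH")
        site_b = make_site(pos=50, ac=4, an=200, carriers=None, cohort="b")
        site_b.counts["b"].carriers = None
        site_b.clnsig, site_b.impact = "Pathogenic", "HIGH"
        g1 = GeneModel(gene_id="GA", chrom="chr1", cds_start=1, cds_end=100)
        g2 = GeneModel(gene_id="GB", chrom="chr1", cds_start=40, cds_end=140)
        out = gb.run_gene_burden(
            [site], [site_b], [g1, g2], flank=0,
            declared_size_a=100, declared_size_b=100,
        )
        panel = Panel(panel_id="P", name="p", gene_ids=["GA", "GB"])
        df = gb.run_panel_burden([panel], out)
        assert df.iloc[0]["ac_a"] == 4  # not 8
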