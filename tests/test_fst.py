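import numpy as np
import pandas as pd
import pytest

from fstscan import (
    ScanParams,
    SweepSimConfig,
    annotate_candidates,
    candidate_regions,
    hudson_fst,
    make_windows,
    scan,
    simulate_gene_annotation,
    simulate_genotypes,
    snp_fst,
    top_windows,
    window_fst,
)
from fstscan.fst import CandidateRegionSet
from fstscan.io import MISSING, GeneModel

from conftest import make_table, two_group_assignment


def wc_anova_oracle(dosages_g1, dosages_g2):
    """Independent Weir-Cockerham oracle via the nested-ANOVA mean squares
    (gametes within individuals within populations), looped per individual.

    Returns (a, b, c) for the alternate allele.
    """
    groups = [np.asarray(dosages_g1), np.asarray(dosages_g2)]
    r = 2
    n_i = [len(g) for g in groups]
    n_tot = sum(n_i)
    p_i = [g.mean() / 2 for g in groups]
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / n_tot

    ssg = ssi = ssp = 0.0
    for g, n, p in zip(groups, n_i, p_i):
        for d in g:
            ssg += 0.5 if d == 1 else 0.0
            ssi += 2 * (d / 2 - p) ** 2
        ssp += 2 * n * (p - p_bar) ** 2
    msg = ssg / n_tot
    msi = ssi / (n_tot - r)
    msp = ssp / (r - 1)
    n_c = (n_tot - sum(n**2 for n in n_i) / n_tot) / (r - 1)
    c = msg
    b = (msi - msg) / 2
    a = (msp - msi) / (2 * n_c)
    return a, b, c


def components_for(dosages_g1, dosages_g2):
    d1, d2 = list(dosages_g1), list(dosages_g2)
    t = make_table([100], [d1 + d2])
    groups = two_group_assignment(len(d1), len(d2))
    return snp_fst(t, groups)


class TestSnpFst:
    def test_worked_example_matches_hand_evaluation(self):
        """Genotype counts (8 hom-ref, 2 het, 0 hom-alt) vs (1, 4, 5)."""
        comp = components_for([0] * 8 + [1] * 2, [0] + [1] * 4 + [2] * 5)
        assert comp.a[0] == pytest.approx(0.1716667, abs=5e-7)
        assert comp.b[0] == pytest.approx(0.0083333, abs=5e-7)
        assert comp.c[0] == pytest.approx(0.15, abs=1e-12)
        assert comp.theta[0] == pytest.approx(0.520202, abs=5e-7)

    def test_fixed_difference_theta_exactly_one(self):
        comp = components_for([0] * 10, [2] * 10)
        assert comp.a[0] == pytest.approx(0.5, abs=1e-12)
        assert comp.b[0] == 0 and comp.c[0] == 0
        assert comp.theta[0] == 1.0

    def test_monomorphic_site_undefined_not_nan_propagated(self):
        comp = components_for([0] * 10, [0] * 10)
        assert comp.a[0] == comp.b[0] == comp.c[0] == 0
        assert not comp.defined[0]
        assert np.isnan(comp.theta[0])

    def test_group_with_no_calls_flagged_undefined(self):
        t = make_table([100], [[MISSING, MISSING, 0, 1]])
        comp = snp_fst(t, two_group_assignment(2, 2))
        assert not comp.defined[0]

    def test_more_than_two_groups_rejected(self):
        from fstscan import GroupAssignment

        t = make_table([100], [[0, 1, 2]])
        ga = GroupAssignment({"s0": "a", "s1": "b", "s2": "c"})
        with pytest.raises(ValueError, match="two groups"):
            snp_fst(t, ga)

    def test_matches_anova_oracle_on_random_configurations(self):
        """Vectorized components equal the loop-based ANOVA oracle to 1e-10
        on 1,000 random genotype configurations."""
        rng = np.random.default_rng(42)
        for _ in range(1_000):
            n1, n2 = rng.integers(2, 15, size=2)
            d1 = rng.integers(0, 3, size=n1)
            d2 = rng.integers(0, 3, size=n2)
            comp = components_for(d1, d2)
            a, b, c = wc_anova_oracle(d1, d2)
            assert comp.a[0] == pytest.approx(a, abs=1e-10)
            assert comp.b[0] == pytest.approx(b, abs=1e-10)
            assert comp.c[0] == pytest.approx(c, abs=1e-10)
            if a + b + c != 0:
                assert comp.theta[0] == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_hudson_agrees_directionally_with_wc(self):
        cfg = SweepSimConfig(
            chrom_length=500_000, snp_density=1 / 200, F_background=0.1, seed=13
        )
        t, g, _ = simulate_genotypes(cfg)
        comp = snp_fst(t, g)
        hud = hudson_fst(t, g)
        ok = comp.defined & ~np.isnan(hud)
        corr = np.corrcoef(comp.theta[ok], hud[ok])[0, 1]
        assert corr > 0.9


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length, starts",
        [
            (100_000, [1, 25_001, 50_001, 75_001]),
            (50_000, [1, 25_001]),
            (10, [1]),
        ],
    )
    def test_grid_arithmetic(self, length, starts):
        win = make_windows({"chr1": length})
        assert list(win["start"]) == starts
        assert (win["end"] - win["start"] + 1 == 50_000).all()


class TestWindowFst:
    def test_snp_contributes_to_both_overlapping_windows(self):
        t = make_table([30_000], [[0] * 10 + [2] * 10])
        comp = snp_fst(t, two_group_assignment(10, 10))
        win = window_fst(comp, make_windows({"chr1": 100_000}))
        assert list(win.loc[win["n_snps"] > 0, "start"]) == [1, 25_001]

    def test_single_snp_window_equals_per_snp_ratio(self):
        t = make_table([60_000], [[0] * 8 + [1] * 2 + [0] + [1] * 4 + [2] * 5])
        comp = snp_fst(t, two_group_assignment(10, 10))
        win = window_fst(comp, make_windows({"chr1": 100_000}))
        hit = win[win["n_snps"] == 1]
        assert np.allclose(hit["fst_weighted"], comp.theta[0])

    def test_ratio_of_sums_aggregation(self):
        """Identical SNPs with (a,b,c)=(0.1,0.05,0.05): window Fst = 0.5."""
        d = [0] * 10 + [2] * 10  # any polymorphic config; override components
        t = make_table(list(range(1_000, 11_000, 1_000)), [d] * 10)
        comp = snp_fst(t, two_group_assignment(10, 10))
        comp.a[:] = 0.1
        comp.b[:] = 0.05
        comp.c[:] = 0.05
        comp.theta[:] = 0.5
        win = window_fst(comp, make_windows({"chr1": 50_000}))
        first = win.iloc[0]
        assert first["n_snps"] == 10
        assert first["fst_weighted"] == pytest.approx(0.5)

    def test_interior_snps_fall_in_exactly_two_windows(self):
        cfg = SweepSimConfig(chrom_length=500_000, snp_density=1 / 250, seed=21)
        t, g, _ = simulate_genotypes(cfg)
        comp = snp_fst(t, g)
        win = window_fst(comp, make_windows(cfg.chrom_lengths))
        n_defined = comp.defined.sum()
        n_first_window_only = (comp.defined & (comp.pos <= 25_000)).sum()
        assert win["n_snps"].sum() == 2 * n_defined - n_first_window_only


class TestTopWindows:
    def _stats(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": 1 + 25_000 * np.arange(n),
                "end": 50_000 + 25_000 * np.arange(n),
                "n_snps": 10,
                "fst_weighted": values,
                "fst_mean": values,
                "eligible": True,
            }
        )

    def test_ceiling_selection(self):
        top = top_windows(self._stats(np.linspace(0, 1, 400)))
        assert len(top) == 4
        top = top_windows(self._stats(np.linspace(0, 1, 399)))
        assert len(top) == 4  # ceil(3.99)

    def test_total_tie_selects_everything(self):
        top = top_windows(self._stats(np.full(100, 0.3)))
        assert len(top) == 100

    def test_empty_eligible_set_rejected(self):
        stats = self._stats(np.array([0.1]))
        stats["eligible"] = False
        with pytest.raises(ValueError, match="eligible"):
            top_windows(stats)


class TestCandidateRegions:
    def _top(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "fst_weighted"]
        )

    def test_flank_extension(self):
        top = self._top([("chr16", 300_001, 350_000, 0.22)])
        regs = candidate_regions(top, chrom_lengths={"chr16": 1_000_000}).regions
        assert list(regs.iloc[0][["start", "end"]]) == [250_001, 400_000]

    def test_extension_clips_at_chromosome_start(self):
        top = self._top([("chr1", 1, 50_000, 0.5)])
        regs = candidate_regions(top).regions
        assert regs.iloc[0]["start"] == 1

    def test_adjacent_windows_merge(self):
        top = self._top(
            [("chr1", 100_001, 150_000, 0.4), ("chr1", 125_001, 175_000, 0.3)]
        )
        regs = candidate_regions(top).regions
        assert len(regs) == 1
        assert regs.iloc[0]["n_windows"] == 2
        assert regs.iloc[0]["max_window_fst"] == 0.4

    def test_distant_windows_stay_separate(self):
        top = self._top(
            [("chr1", 1, 50_000, 0.4), ("chr1", 500_001, 550_000, 0.3)]
        )
        assert len(candidate_regions(top).regions) == 2


class TestAnnotateCandidates:
    def _region_set(self):
        return CandidateRegionSet(
            regions=pd.DataFrame(
                [("chr1", 250_001, 400_000, 1, 0.22)],
                columns=["chrom", "start", "end", "n_windows", "max_window_fst"],
            )
        )

    def test_one_bp_overlap_is_candidate(self):
        genes = [GeneModel("g1", "chr1", 399_950, 401_000)]
        out = annotate_candidates(self._region_set(), genes)
        assert list(out.candidate_genes["gene_id"]) == ["g1"]
        assert out.candidate_genes.iloc[0]["best_window_fst"] == 0.22

    def test_adjacent_gene_is_not_candidate(self):
        genes = [GeneModel("g1", "chr1", 400_001, 401_000)]
        out = annotate_candidates(self._region_set(), genes)
        assert out.candidate_genes.empty

    def test_no_genes_gives_empty_list(self):
        out = annotate_candidates(self._region_set(), [])
        assert out.candidate_genes.empty


class TestScan:
    def test_planted_sweep_recovered_and_deterministic(self, tmp_path):
        cfg = SweepSimConfig(
            chrom_length=2_000_000, snp_density=1 / 400, F_background=0.05,
            sweep_regions=[("chr1", 1_000_001, 1_100_000, 0.3)], seed=17,
        )
        t, g, _ = simulate_genotypes(cfg)
        genes = simulate_gene_annotation(40, cfg.chrom_lengths, seed=17)
        res1 = scan(t, g, genes, cfg.chrom_lengths)
        res2 = scan(t, g, genes, cfg.chrom_lengths)
        pd.testing.assert_frame_equal(res1.windows, res2.windows)
        regs = res1.candidates.regions
        assert (
            (regs["chrom"] == "chr1")
            & (regs["start"] <= 1_100_000)
            & (regs["end"] >= 1_000_001)
        ).any()

    def test_top_fraction_one_covers_every_eligible_window(self):
        cfg = SweepSimConfig(chrom_length=300_000, snp_density=1 / 300, seed=19)
        t, g, _ = simulate_genotypes(cfg)
        params = ScanParams(top_fraction=1.0)
        res = scan(t, g, [], cfg.chrom_lengths, params)
        assert len(res.top) == int(res.windows["eligible"].sum())
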