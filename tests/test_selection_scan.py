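import numpy as np
import pytest
from scipy import stats

from driftscan.drift_simulator import PopulationTree, SelectionSpec, simulate_dataset
from driftscan.genotype_io import allele_frequencies
from driftscan.selection_scan import (
    KinshipF,
    SelectedRegion,
    build_kinship,
    call_fst_regions,
    estimate_pi0,
    flk,
    global_fst,
    per_snp_fst,
    qvalues,
    reynolds_distances,
    run_one_vs_rest,
    run_scan,
    smooth_fst,
)

from conftest import make_snps
from test_f_statistics import freqs_from


def wc_theta_oracle(p_list, n_list):
    """Brute-force Weir-Cockerham theta from the published component sums."""
    r = len(p_list)
    nbar = sum(n_list) / r
    nc = (sum(n_list) - sum(n**2 for n in n_list) / sum(n_list)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_list, p_list)) / sum(n_list)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_list, p_list)) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    return a / (a + b)


class TestPerSnpFst:
    def test_identical_freqs_plain_zero(self):
        fr = freqs_from([[0.3], [0.3], [0.3]], [[100], [100], [100]])
        assert per_snp_fst(fr, "plain")[0] == pytest.approx(0.0)

    def test_fixed_difference_plain_one(self):
        fr = freqs_from([[1.0], [0.0]], [[100], [100]])
        assert per_snp_fst(fr, "plain")[0] == pytest.approx(1.0)

    def test_wc_two_pop_worked_example(self):
        # counts 30/100 and 70/100 (allele2/haploids)
        fr = freqs_from([[0.3], [0.7]], [[100], [100]])
        assert per_snp_fst(fr)[0] == pytest.approx(wc_theta_oracle([0.3, 0.7], [100, 100]), abs=1e-12)

    def test_wc_matches_oracle_random(self, rng):
        m = 50
        p = rng.uniform(0.05, 0.95, size=(4, m))
        n = (rng.integers(10, 80, size=(4, m)) * 2).astype(float)
        fr = freqs_from(p, n.astype(int))
        vals = per_snp_fst(fr)
        for j in range(m):
            oracle = wc_theta_oracle(list(p[:, j]), list(n[:, j]))
            assert vals[j] == pytest.approx(oracle, abs=1e-12)

    def test_monomorphic_is_nan(self):
        fr = freqs_from([[0.0, 0.5], [0.0, 0.5]], [[20, 20], [20, 20]], pops=["A", "B"])
        vals = per_snp_fst(fr)
        assert np.isnan(vals[0])

    def test_single_population_raises(self):
        fr = freqs_from([[0.5]], [[20]])
        with pytest.raises(ValueError, match="2 populations"):
            per_snp_fst(fr)

    def test_global_fst_in_simulation_window(self):
        tree = PopulationTree.from_newick("(A:0.1,B:0.1);")
        ds, _ = simulate_dataset(tree, 10_000, 100, seed=31)
        assert 0.085 <= global_fst(allele_frequencies(ds)) <= 0.115


class TestSmoothFst:
    def test_constant_sequence(self):
        snps = make_snps(7)
        np.testing.assert_allclose(smooth_fst(np.full(7, 0.4), snps, 3), 0.4)

    def test_window_one_is_identity(self, rng):
        snps = make_snps(9)
        x = rng.random(9)
        np.testing.assert_allclose(smooth_fst(x, snps, 1), x)

    def test_hand_computed_truncated_means(self):
        snps = make_snps(5)
        out = smooth_fst(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), snps, 3)
        np.testing.assert_allclose(out, [0.5, 1 / 3, 2 / 3, 1 / 3, 0.5])

    def test_windows_do_not_cross_chromosomes(self):
        snps = make_snps(3, chrom="1") + make_snps(3, chrom="2")
        x = np.array([0.0, 0.0, 0.0, 9.0, 9.0, 9.0])
        out = smooth_fst(x, snps, 3)
        np.testing.assert_allclose(out[:3], 0.0)
        np.testing.assert_allclose(out[3:], 9.0)

    def test_nan_ignored_within_window(self):
        snps = make_snps(3)
        out = smooth_fst(np.array([1.0, np.nan, 3.0]), snps, 3)
        assert out[1] == pytest.approx(2.0)

    def test_unsorted_raises(self):
        snps = make_snps(3)
        snps = [snps[1], snps[0], snps[2]]
        with pytest.raises(ValueError, match="sorted"):
            smooth_fst(np.zeros(3), snps, 3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_fst(np.zeros(4), make_snps(4), 4)

    def test_linearity(self, rng):
        snps = make_snps(40)
        x, y = rng.random(40), rng.random(40)
        a, b = 2.5, -1.0
        lhs = smooth_fst(a * x + b * y, snps, 5)
        rhs = a * smooth_fst(x, snps, 5) + b * smooth_fst(y, snps, 5)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestCallRegions:
    def test_iid_flags_about_five_percent(self, rng):
        snps = make_snps(10_000)
        vals = rng.random(10_000)
        regions, _ = call_fst_regions(snps, vals, 0.95, max_gap_snps=0)
        flagged = sum(r.n_snps for r in regions)
        assert 0.043 * 10_000 <= flagged <= 0.057 * 10_000

    def test_all_equal_zero_regions(self):
        snps = make_snps(100)
        regions, _ = call_fst_regions(snps, np.full(100, 0.2))
        assert regions == []

    def test_quantile_is_type7(self, rng):
        snps = make_snps(101)
        vals = rng.random(101)
        _, threshold = call_fst_regions(snps, vals, 0.95)
        assert threshold == pytest.approx(np.quantile(vals, 0.95))

    def test_gap_merging(self):
        snps = make_snps(30)
        vals = np.zeros(30)
        vals[[10, 12, 20]] = 1.0  # gap of 1 between 10 and 12
        regions, _ = call_fst_regions(snps, vals, 0.9, max_gap_snps=1)
        assert len(regions) == 2
        first = regions[0]
        # n_snps counts above-threshold members only; the span bridges the gap
        assert (first.start_bp, first.end_bp, first.n_snps) == (
            snps[10].pos_bp,
            snps[12].pos_bp,
            2,
        )

    def test_few_snps_warns(self):
        with pytest.warns(UserWarning, match="quantile"):
            call_fst_regions(make_snps(5), np.arange(5.0))

    def test_clustered_high_drift_loci_form_one_region(self):
        tree = PopulationTree.from_newick("(A:0.02,B:0.02);")
        idx = np.arange(500, 550)
        ds, _ = simulate_dataset(
            tree, 5000, 50, selected_spec=[SelectionSpec("A", idx, c_sel=0.6)],
            seed=32, n_chroms=5,
        )
        fst = per_snp_fst(allele_frequencies(ds))
        smoothed = smooth_fst(fst, ds.snps, 9)
        regions, _ = call_fst_regions(ds.snps, smoothed, 0.95, max_gap_snps=2)
        best = max(regions, key=lambda r: r.n_snps)
        inside = [
            j
            for j in idx
            if ds.snps[j].chrom == best.chrom
            and best.start_bp <= ds.snps[j].pos_bp <= best.end_bp
        ]
        assert len(inside) >= 40


class TestKinship:
    def test_two_pops_plus_outgroup_diagonal(self):
        tree = PopulationTree.from_newick("((A:0.05,B:0.05):0.03,O:0.1);", outgroup="O")
        ds, _ = simulate_dataset(tree, 4000, 60, seed=33)
        kin = build_kinship(allele_frequencies(ds), "O")
        assert kin.populations == ["A", "B"]
        # rooted on the outgroup branch, two ingroup pops form a star: off-diagonal ~ 0
        assert abs(kin.F[0, 1]) < 0.25 * min(kin.F[0, 0], kin.F[1, 1])

    def test_nj_recovers_additive_topology(self):
        # additive distances from tree ((A,B),(C,D)) with known branch lengths
        fr = freqs_from(np.full((4, 10), 0.5), np.full((4, 10), 20), pops=list("ABCD"))
        # bypass frequency-based distances: call skbio nj directly via build path
        from skbio import DistanceMatrix
        from skbio.tree import nj

        D = np.array(
            [
                [0.0, 0.10, 0.30, 0.30],
                [0.10, 0.0, 0.30, 0.30],
                [0.30, 0.30, 0.0, 0.10],
                [0.30, 0.30, 0.10, 0.0],
            ]
        )
        tree = nj(DistanceMatrix(D, ids=list("ABCD")))
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"} or {
            t.name for t in ab.tips()
        } == {"C", "D"}
        # pairwise path distances reproduce the input exactly (additive input)
        for x, y, d in [("A", "B", 0.1), ("A", "C", 0.3), ("C", "D", 0.1)]:
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(d, abs=1e-10)

    def test_recovers_true_kinship_within_20pct(self):
        nwk = "(((A:0.06,B:0.06):0.04,(C:0.08,D:0.05):0.05):0.05,O:0.1);"
        tree = PopulationTree.from_newick(nwk, outgroup="O")
        ds, _ = simulate_dataset(tree, 20_000, 100, seed=34)
        kin = build_kinship(allele_frequencies(ds), "O")
        pops, F_true = tree.kinship_matrix(exclude=["O"])
        order = [kin.populations.index(p) for p in pops]
        F_est = kin.F[np.ix_(order, order)]
        sig = np.abs(F_true) > 0.01
        rel = np.abs(F_est[sig] - F_true[sig]) / F_true[sig]
        assert rel.max() < 0.2

    def test_reynolds_distances_symmetric_nonnegative(self):
        tree = PopulationTree.from_newick("((A:0.05,B:0.05):0.03,O:0.1);")
        ds, _ = simulate_dataset(tree, 2000, 40, seed=35)
        D = reynolds_distances(allele_frequencies(ds))
        assert np.allclose(D, D.T)
        assert (D >= 0).all() and np.allclose(np.diag(D), 0)

    def test_needs_three_populations(self):
        fr = freqs_from([[0.5], [0.4]], [[20], [20]], pops=["A", "O"])
        with pytest.raises(ValueError, match="3 populations"):
            build_kinship(fr, "O")


class TestFLK:
    def test_equal_freqs_zero_statistic(self):
        kin = KinshipF(["A", "B", "C"], np.diag([0.1, 0.1, 0.1]))
        fr = freqs_from(np.full((3, 5), 0.4), np.full((3, 5), 200), pops=["A", "B", "C"])
        stat, pval = flk(fr, kin, sampling_correction=False)
        np.testing.assert_allclose(stat, 0.0, atol=1e-12)
        np.testing.assert_allclose(pval, 1.0)

    def test_star_tree_reduces_to_lk_form(self, rng):
        f = 0.07
        r = 4
        kin = KinshipF([f"P{i}" for i in range(r)], f * np.eye(r))
        p = rng.uniform(0.2, 0.8, size=(r, 30))
        fr = freqs_from(p, np.full((r, 30), 100))
        stat, _ = flk(fr, kin, sampling_correction=False)
        p0 = p.mean(axis=0)  # GLS with F = f*I is the plain mean
        lk = ((p - p0) ** 2).sum(axis=0) / (f * p0 * (1 - p0))
        np.testing.assert_allclose(stat, lk, atol=1e-12)

    def test_three_pop_toy_against_linear_algebra_oracle(self):
        F = np.array([[0.1, 0.05, 0.0], [0.05, 0.1, 0.0], [0.0, 0.0, 0.2]])
        p = np.array([0.5, 0.6, 0.9])
        kin = KinshipF(["A", "B", "C"], F)
        fr = freqs_from(p[:, None], np.full((3, 1), 1000), pops=["A", "B", "C"])
        stat, _ = flk(fr, kin, sampling_correction=False)
        Finv = np.linalg.inv(F)
        one = np.ones(3)
        p0 = (one @ Finv @ p) / (one @ Finv @ one)
        resid = p - p0
        oracle = resid @ Finv @ resid / (p0 * (1 - p0))
        assert stat[0] == pytest.approx(oracle, abs=1e-10)

    def test_allele_relabeling_invariance(self, rng):
        F = np.array([[0.1, 0.02], [0.02, 0.15]])
        kin = KinshipF(["A", "B"], F)
        p = rng.uniform(0.1, 0.9, size=(2, 40))
        n = np.full((2, 40), 60)
        s1, _ = flk(freqs_from(p, n, pops=["A", "B"]), kin)
        s2, _ = flk(freqs_from(1 - p, n, pops=["A", "B"]), kin)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_fixed_ancestral_estimate_excluded(self):
        kin = KinshipF(["A", "B"], np.diag([0.1, 0.1]))
        fr = freqs_from([[0.0, 0.5], [0.0, 0.5]], [[20, 20], [20, 20]], pops=["A", "B"])
        stat, _ = flk(fr, kin)
        assert np.isnan(stat[0]) and np.isfinite(stat[1])

    def test_null_calibration_true_kinship(self):
        nwk = "(((A:0.06,B:0.06):0.04,(C:0.08,D:0.05):0.05):0.05,O:0.1);"
        tree = PopulationTree.from_newick(nwk, outgroup="O")
        ds, _ = simulate_dataset(tree, 20_000, 200, seed=36)
        pops, F = tree.kinship_matrix(exclude=["O"])
        stat, _ = flk(allele_frequencies(ds), KinshipF(pops, F))
        mean = np.nanmean(stat)
        exceed = np.nanmean(stat > stats.chi2.ppf(0.95, df=3))
        assert abs(mean - 3) <= 0.15
        assert 0.04 <= exceed <= 0.06

    def test_null_calibration_estimated_kinship(self):
        nwk = "(((A:0.06,B:0.06):0.04,(C:0.08,D:0.05):0.05):0.05,O:0.1);"
        tree = PopulationTree.from_newick(nwk, outgroup="O")
        ds, _ = simulate_dataset(tree, 20_000, 200, seed=37)
        fr = allele_frequencies(ds)
        stat, _ = flk(fr, build_kinship(fr, "O"))
        assert abs(np.nanmean(stat) - 3) <= 0.3


class TestQValues:
    def test_single_p_with_pi0_one(self):
        np.testing.assert_allclose(qvalues(np.array([0.03]), pi0=1.0), [0.03])

    def test_step_up_minima_oracle(self):
        # enumerate q(p_(i)) = min_{t >= p_(i)} pi0 * m * t / rank(t) by hand:
        # ranks 1..5 give 0.05, 0.05, 0.05, 0.05, 0.9 -> running minima from the top
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.9])
        q = qvalues(p, pi0=1.0)
        m = 5
        oracle = [
            min(1.0 * m * t / (rank + 1) for rank, t in enumerate(p) if t >= pi)
            for pi in p
        ]
        np.testing.assert_allclose(q, oracle, atol=1e-12)
        np.testing.assert_allclose(q, [0.05, 0.05, 0.05, 0.05, 0.9], atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_pi0_uniform_near_one(self, rng):
        p = rng.uniform(size=10_000)
        assert 0.9 <= estimate_pi0(p) <= 1.1

    def test_pi0_fixed_lambda(self, rng):
        p = rng.uniform(size=10_000)
        pi0 = estimate_pi0(p, method="fixed")
        assert pi0 == pytest.approx((p > 0.5).sum() / 5000, abs=1e-12)

    def test_nan_passthrough(self):
        q = qvalues(np.array([0.01, np.nan, 0.5]), pi0=1.0)
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.0, 0.5]))
        with pytest.raises(ValueError, match="finite"):
            qvalues(np.array([np.nan]))


class TestRunScan:
    def test_one_vs_rest_yields_one_table_per_population(self):
        tree = PopulationTree.from_newick(
            "((((A:0.02,B:0.02):0.02,C:0.03):0.02,E:0.05):0.03,O:0.1);", outgroup="O"
        )
        ds, _ = simulate_dataset(tree, 1000, 15, seed=38, n_chroms=2)
        results = run_one_vs_rest(ds, outgroup="O")
        assert set(results) == {"A", "B", "C", "E"}
        for res in results.values():
            assert len(res.table) == 1000

    def test_null_scan_flk_flags_almost_nothing(self):
        nwk = "(((A:0.02,B:0.02):0.02,(C:0.02,E:0.02):0.02):0.02,O:0.1);"
        tree = PopulationTree.from_newick(nwk, outgroup="O")
        ds, _ = simulate_dataset(tree, 10_000, 40, seed=39)
        res = run_scan(ds, outgroup="O")
        assert res.flk_flagged.mean() <= 0.01
        assert res.flk_regions == []

    def test_selection_scenario_intersection_enriched(self):
        nwk = "(((A:0.02,B:0.02):0.02,(C:0.02,E:0.02):0.02):0.02,O:0.1);"
        tree = PopulationTree.from_newick(nwk, outgroup="O")
        sel = np.arange(300, 360)
        ds, _ = simulate_dataset(
            tree, 8000, 40, selected_spec=[SelectionSpec("A", sel, c_sel=0.6)], seed=40
        )
        res = run_scan(ds, outgroup="O")
        both = res.both_flagged
        assert both.any()
        frac_in_sel = both[sel].mean()
        frac_elsewhere = np.delete(both, sel).mean()
        assert frac_in_sel > 10 * max(frac_elsewhere, 1e-4)

    def test_no_outgroup_skips_flk(self):
        tree = PopulationTree.from_newick("(A:0.02,B:0.02);")
        ds, _ = simulate_dataset(tree, 500, 15, seed=41)
        res = run_scan(ds)
        assert np.isnan(res.table["flk"]).all()
        assert res.kinship is None

    def test_stage_name_in_error(self):
        tree = PopulationTree.from_newick("(A:0.02,B:0.02);")
        ds, _ = simulate_dataset(tree, 500, 15, seed=42)
        with pytest.raises(RuntimeError, match=r"\[grouping\]"):
            run_scan(ds, groups={"A": "g", "B": "g"})

    def test_fst_negative_clamped_in_table_only(self):
        tree = PopulationTree.from_newick("(A:0.01,B:0.01);")
        ds, _ = simulate_dataset(tree, 2000, 30, seed=43)
        res = run_scan(ds)
        assert (res.table["fst"] >= 0).all()
        assert (res.table["fst_raw"] < 0).any()  # WC goes negative on null SNPs

    def test_outputs_written(self, tmp_path):
        tree = PopulationTree.from_newick("((A:0.05,B:0.05):0.03,O:0.1);", outgroup="O")
        ds, _ = simulate_dataset(tree, 1000, 20, seed=44, n_chroms=2)
        res = run_scan(ds, outgroup="O")
        res.write(tmp_path, stem="s")
        assert (tmp_path / "s_table.tsv").exists()
        assert (tmp_path / "s_regions.tsv").exists()
        assert (tmp_path / "s_manhattan.tsv").exists()


class TestSelectedRegion:
    def test_validation(self):
        with pytest.raises(ValueError):
            SelectedRegion("1", 100, 50, 3, 1.0, "FST")
        with pytest.raises(ValueError):
            SelectedRegion("1", 100, 200, 0, 1.0, "FST")
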