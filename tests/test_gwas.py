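import numpy as np
import pandas as pd
import pytest

from admixgwas import gwas, io_core
from admixgwas.gwas import (cluster_qtls, control_fdr, filter_snps,
                            m1_battery, m2_battery, m3_battery)
from admixgwas.io_core import MISSING, MarkerMap


#: the 16 M3 hypotheses: name -> (type, coefficients over
#: (Delta_DD, Delta_DA, Delta_FA, Delta_FF), tests a background interaction)
M3_EXPECTED = {
    "DD": ("simple", (1, 0, 0, 0), False),
    "DA": ("simple", (0, 1, 0, 0), False),
    "FA": ("simple", (0, 0, 1, 0), False),
    "FF": ("simple", (0, 0, 0, 1), False),
    "DD+FF": ("general", (1, 0, 0, 1), False),
    "DD+DA": ("general", (1, 1, 0, 0), False),
    "FF+FA": ("general", (0, 0, 1, 1), False),
    "DA+FA": ("general", (0, 1, 1, 0), False),
    "DD+DA+FA+FF": ("general", (1, 1, 1, 1), False),
    "DD-FF": ("divergent", (1, 0, 0, -1), False),
    "DD-DA": ("divergent", (1, -1, 0, 0), True),
    "FF-FA": ("divergent", (0, 0, -1, 1), True),
    "DA-FA": ("divergent", (0, 1, -1, 0), False),
    "(DD+DA)-(FF+FA)": ("divergent", (1, 1, -1, -1), False),
    "(DD+FF)-(DA+FA)": ("divergent", (1, -1, -1, 1), True),
    "(DD-DA)-(FF-FA)": ("divergent", (1, -1, 1, -1), True),
}


class TestBatteries:
    def test_m3_battery_has_sixteen_exact_rows(self):
        specs = {s.name: s for s in m3_battery()}
        assert len(specs) == 16
        for name, (typ, coeffs, inter) in M3_EXPECTED.items():
            assert specs[name].type == typ
            assert specs[name].coefficients == coeffs
            assert specs[name].interaction == inter

    def test_simple_specs_are_unit_rows(self):
        simple = [s for s in m3_battery() if s.type == "simple"]
        rows = [tuple(s.coefficients) for s in simple]
        assert sorted(rows) == sorted(map(tuple, np.eye(4, dtype=int)))

    def test_m2_battery(self):
        names = [(s.name, s.type, s.coefficients) for s in m2_battery()]
        assert names == [("D", "simple", (1, 0)), ("F", "simple", (0, 1)),
                         ("D+F", "general", (1, 1)), ("D-F", "divergent", (1, -1))]
        assert len(m1_battery()) == 1

    def test_design_coefficients_expand_to_allele_contrasts(self):
        spec = next(s for s in m3_battery() if s.name == "(DD+DA)-(FF+FA)")
        c = spec.design_coefficients()
        space = io_core.STATE_SPACE["M3"]
        expected = np.zeros(9)
        for base, w in zip(("DD", "DA", "FA", "FF"), (1, 1, -1, -1)):
            expected[1 + space.index(f"1{base}")] = w
            expected[1 + space.index(f"0{base}")] = -w
        np.testing.assert_array_equal(c, expected)


class TestFiltering:
    def _codes(self, count_minor, n=300):
        codes = np.zeros((n, 1), dtype=np.int8)
        codes[:count_minor, 0] = 0
        codes[count_minor:, 0] = 1
        return codes

    def test_minor_state_threshold_boundary(self):
        mmap = MarkerMap(["a"], ["1"], [100])
        assert len(filter_snps(self._codes(9), mmap, "M1").kept) == 0
        assert len(filter_snps(self._codes(10), mmap, "M1").kept) == 1

    def test_absent_state_excludes_marker(self):
        # marker fixed within one required combination: minor state count 0
        codes = np.full((40, 1), 0, dtype=np.int8)
        mmap = MarkerMap(["a"], ["1"], [100])
        assert len(filter_snps(codes, mmap, "M1").kept) == 0

    def test_redundant_marker_aliased_to_first(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, 40).astype(np.int8)
        other = rng.integers(0, 2, 40).astype(np.int8)
        codes = np.stack([col, other, col], axis=1)
        codes[:20, 1] = 0; codes[20:, 1] = 1
        mmap = MarkerMap(["a", "b", "c"], ["1", "1", "1"], [100, 200, 300])
        res = filter_snps(codes, mmap, "M1")
        assert list(mmap.marker_ids[res.kept]) == ["a", "b"]
        assert res.aliases == {"c": "a"}


class TestBuildDesign:
    def test_one_indicator_per_line(self):
        codes = np.array([1, 2, 5, 6], dtype=np.int8)  # 1DD, 0DA, 1FA, 0FF
        X, valid = gwas.build_design(codes, "M3")
        assert X.shape == (4, 9)
        assert valid.all()
        np.testing.assert_array_equal(X[:, 0], 1)
        np.testing.assert_array_equal(X[:, 1:].sum(axis=1), 1)

    def test_undetermined_lines_dropped(self):
        codes = np.array([0, MISSING, 1], dtype=np.int8)
        X, valid = gwas.build_design(codes, "M1")
        assert valid.tolist() == [True, False, True]
        assert X.shape == (2, 3)

    def test_all_contrasts_estimable_with_all_states_present(self):
        from admixgwas import mixedmodel
        rng = np.random.default_rng(1)
        codes = np.repeat(np.arange(8, dtype=np.int8), 12)
        X, _ = gwas.build_design(codes, "M3")
        fit = mixedmodel.gls_fit(rng.normal(size=len(codes)), X)
        for spec in m3_battery():
            assert fit.estimable(spec.design_coefficients())


class TestFDR:
    def test_all_ones_no_discoveries(self):
        df = pd.DataFrame({"p": np.ones(10)})
        out = control_fdr(df, levels=(0.05, 0.20))
        assert out["significant_5"].sum() == 0
        assert out["significant_20"].sum() == 0

    def test_step_up_hand_example(self):
        # sorted p (0.001, 0.01, 0.02, 0.9); k/m * 0.05 = (0.0125, .025, .0375, .05)
        # largest k with p_(k) <= k alpha / m is 3 -> 3 discoveries
        df = pd.DataFrame({"p": [0.9, 0.001, 0.02, 0.01]})
        out = control_fdr(df, levels=(0.05,))
        assert out["significant_5"].sum() == 3
        assert not out.loc[0, "significant_5"]

    def test_discovery_monotonicity_in_level(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"p": rng.uniform(size=500) ** 2})
        out = control_fdr(df)
        assert (out["significant_5"] <= out["significant_20"]).all()
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestQTLClustering:
    def _sig(self, positions_mbp, ps=None, hyp="DD"):
        n = len(positions_mbp)
        return pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(n)],
            "chromosome": ["1"] * n,
            "position": [int(p * 1e6) for p in positions_mbp],
            "hypothesis": [hyp] * n,
            "p": ps if ps is not None else [1e-6] * n,
        })

    def test_three_mbp_chaining(self):
        clusters = cluster_qtls(self._sig([1.0, 2.5, 6.0]))
        assert len(clusters) == 2
        assert clusters[0].members == ["m0", "m1"]
        assert clusters[1].members == ["m2"]

    def test_single_marker_single_qtl(self):
        clusters = cluster_qtls(self._sig([10.0]))
        assert len(clusters) == 1 and clusters[0].span == 0

    def test_lead_marker_min_p_tie_smaller_position(self):
        clusters = cluster_qtls(self._sig([1.0, 2.0], ps=[1e-8, 1e-8]))
        assert clusters[0].lead_marker == "m0"
        clusters = cluster_qtls(self._sig([1.0, 2.0], ps=[1e-4, 1e-8]))
        assert clusters[0].lead_marker == "m1"

    def test_model_level_merge_of_overlapping_hypotheses(self):
        a = self._sig([1.0, 2.0], hyp="DD")
        b = self._sig([2.0, 4.0], hyp="DD+FF")
        clusters = cluster_qtls(pd.concat([a, b], ignore_index=True))
        merged = gwas.merge_clusters(clusters)
        assert len(clusters) == 2 and len(merged) == 1


@pytest.fixture(scope="module")
def m3_run(sim_panel):
    ids = sim_panel.genotypes.markers.marker_ids[:60]
    return gwas.run_gwas(sim_panel.phenotypes, sim_panel.genotypes,
                         sim_panel.pedigree, sim_panel.tracks, model="M3",
                         test_markers=list(ids))


class TestRunGwas:
    def test_battery_closure_identities(self, m3_run):
        """Every general/divergent estimate equals the same linear
        combination of the four simple estimates, exactly per marker."""
        wide = m3_run.results.pivot(index="marker_id", columns="hypothesis",
                                    values="estimate")
        base = wide[["DD", "DA", "FA", "FF"]].to_numpy()
        for name, (_t, coeffs, _i) in M3_EXPECTED.items():
            expected = base @ np.array(coeffs, float)
            scale = np.abs(base).max() + 1.0
            np.testing.assert_allclose(wide[name], expected,
                                       atol=1e-9 * scale)

    def test_m2_sum_difference_identity(self, sim_panel):
        ids = sim_panel.genotypes.markers.marker_ids[:40]
        run = gwas.run_gwas(sim_panel.phenotypes, sim_panel.genotypes,
                            sim_panel.pedigree, sim_panel.tracks, model="M2",
                            test_markers=list(ids))
        wide = run.results.pivot(index="marker_id", columns="hypothesis",
                                 values="estimate")
        np.testing.assert_allclose(wide["D+F"] + wide["D-F"], 2 * wide["D"],
                                   atol=1e-9 * (np.abs(wide.to_numpy()).max() + 1))

    def test_m1_pooled_with_background_effect(self, sim_panel):
        ids = sim_panel.genotypes.markers.marker_ids[:10]
        run = gwas.run_gwas(sim_panel.phenotypes, sim_panel.genotypes,
                            sim_panel.pedigree, sim_panel.tracks, model="M1",
                            m1_pooled=True, test_markers=list(ids))
        assert len(run.lines) == sim_panel.genotypes.n_lines
        assert (run.results["p"] > 0).all()

    def test_two_step_close_to_full_refit(self, sim_panel):
        """The plugged-covariance approximation tracks the exact per-SNP
        ReML refit closely on null data."""
        ids = list(sim_panel.genotypes.markers.marker_ids[:15])
        fast = gwas.run_gwas(sim_panel.phenotypes, sim_panel.genotypes,
                             sim_panel.pedigree, sim_panel.tracks, model="M2",
                             test_markers=ids)
        slow = gwas.run_gwas(sim_panel.phenotypes, sim_panel.genotypes,
                             sim_panel.pedigree, sim_panel.tracks, model="M2",
                             test_markers=ids, refit_reml=True)
        a = fast.results.set_index(["marker_id", "hypothesis"])["p"]
        b = slow.results.set_index(["marker_id", "hypothesis"])["p"]
        common = a.index.intersection(b.index)
        assert len(common) >= 16
        lp = np.corrcoef(np.log(a[common]), np.log(b[common]))[0, 1]
        assert lp > 0.99
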