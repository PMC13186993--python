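import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from gvortho import interactome as ia
from gvortho.io_formats import AbundanceMatrix

from conftest import make_matrix


def preprocessed(values, **kwargs):
    return ia.preprocess_abundance(make_matrix(np.asarray(values, float),
                                               **kwargs))


class TestPreprocess:
    def test_contaminants_removed(self):
        vals = np.full((3, 6), 100.0)
        m = make_matrix(vals, contaminants={"p0": True})
        out = ia.preprocess_abundance(m)
        assert "p0" not in out.protein_ids
        assert len(out.protein_ids) == 2

    def test_min_reps_in_any_one_condition_suffices(self):
        # p0: 3 bait reps, 0 control reps -> kept (>=3 in one condition).
        # p1: 2 bait reps, 2 control reps -> dropped.
        vals = np.array([
            [4.0, 5.0, 6.0, np.nan, np.nan, np.nan],
            [4.0, 5.0, np.nan, 6.0, 7.0, np.nan],
            [4.0, 5.0, 6.0, 7.0, 8.0, 9.0],
        ])
        out = ia.preprocess_abundance(make_matrix(vals))
        assert out.protein_ids == ["p0", "p2"]

    def test_require_both_conditions_is_stricter(self):
        vals = np.array([
            [4.0, 5.0, 6.0, np.nan, np.nan, np.nan],
            [4.0, 5.0, 6.0, 7.0, 8.0, 9.0],
        ])
        out = ia.preprocess_abundance(make_matrix(vals),
                                      require_both_conditions=True)
        assert out.protein_ids == ["p1"]

    def test_quantified_counts_are_pre_imputation(self):
        vals = np.array([
            [4.0, 5.0, 6.0, np.nan, np.nan, np.nan],
            [4.0, 5.0, 6.0, 7.0, 8.0, 9.0],
        ])
        out = ia.preprocess_abundance(make_matrix(vals))
        assert out.quantified_counts.loc["p0", "bait"] == 3
        assert out.quantified_counts.loc["p0", "control"] == 0
        # ... even though the output matrix itself is fully imputed
        assert not out.intensities.isna().to_numpy().any()

    def test_median_centering(self):
        # after normalization every sample's median log2 intensity is equal
        rng = np.random.default_rng(0)
        vals = 2.0 ** rng.uniform(10, 20, size=(30, 6))
        out = preprocessed(vals)
        medians = out.intensities.median(axis=0)
        assert np.allclose(medians, medians.iloc[0])

    def test_mad_equalized_across_samples(self):
        rng = np.random.default_rng(1)
        vals = 2.0 ** rng.uniform(10, 20, size=(50, 6))
        vals[:, 0] = vals[:, 0] ** 1.2  # widen one sample
        out = preprocessed(vals)

        def mad(col):
            med = np.median(col)
            return np.median(np.abs(col - med))

        mads = out.intensities.apply(lambda c: mad(c.to_numpy()))
        assert np.allclose(mads, mads.iloc[0])

    def test_normalization_preserves_log2_differences(self):
        # a protein 4x higher in bait keeps a log2FC near 2 after
        # normalization (the scale-preserving property fold-change
        # thresholds rely on)
        rng = np.random.default_rng(2)
        base = 2.0 ** rng.uniform(18, 22, size=(100, 6))
        base[0, :3] = base[0, 3:] * 4.0
        out = preprocessed(base)
        row = out.intensities.loc["p0"]
        lfc = row[:3].mean() - row[3:].mean()
        assert lfc == pytest.approx(2.0, abs=0.35)

    def test_condition_absent_values_get_low_quantile(self):
        rng = np.random.default_rng(3)
        vals = 2.0 ** rng.uniform(10, 20, size=(40, 6))
        vals[0, 3:] = np.nan  # absent from control
        out = ia.preprocess_abundance(make_matrix(vals),
                                      normalization="none")
        logged = np.log2(vals)
        for j, s in enumerate(out.sample_ids[3:], start=3):
            expected = np.nanquantile(logged[:, j], 0.025)
            assert out.intensities.loc["p0", s] == pytest.approx(expected)

    def test_partial_missingness_regressed_from_neighbours(self):
        # p0 tracks p1..p5 exactly (shifted copies); its one missing cell
        # must be recovered almost exactly by the regression imputer.
        rng = np.random.default_rng(4)
        profile = rng.uniform(12, 18, size=6)
        vals = np.vstack([2.0 ** (profile + d)
                          for d in [0.0, 0.5, 1.0, 1.5, 2.0, 2.5]])
        extra = 2.0 ** rng.uniform(10, 20, size=(20, 6))
        vals = np.vstack([vals, extra])
        truth = math.log2(vals[0, 1])
        vals[0, 1] = np.nan
        out = ia.preprocess_abundance(make_matrix(vals),
                                      normalization="none")
        assert out.intensities.iloc[0, 1] == pytest.approx(truth, abs=0.05)

    def test_already_logged_matrix_rejected(self):
        m = make_matrix(np.full((2, 6), 10.0))
        m.log_scale = True
        with pytest.raises(ValueError, match="log"):
            ia.preprocess_abundance(m)

    def test_unknown_normalization_rejected(self):
        with pytest.raises(ValueError, match="normalization"):
            ia.preprocess_abundance(make_matrix(np.full((4, 6), 10.0)),
                                    normalization="quantile")


def moderated_p_oracle(xb, xc):
    """Independent reimplementation of the empirical-Bayes moderated t-test.

    Uses scipy brentq root finding for the trigamma inverse (the library
    uses Newton iteration) and follows the published procedure: fit
    (d0, s0^2) by method of moments on log variances, shrink, test against
    t(d0 + d) capped at the pooled residual df.
    """
    xb, xc = np.asarray(xb), np.asarray(xc)
    nb, nc = xb.shape[1], xc.shape[1]
    d = nb + nc - 2
    s2 = (((xb - xb.mean(1, keepdims=True)) ** 2).sum(1)
          + ((xc - xc.mean(1, keepdims=True)) ** 2).sum(1)) / d
    s2f = np.maximum(s2, 1e-5 * np.median(s2))
    z = np.log(s2f)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2)
    if evar <= 0:
        d0, s0 = 1e6, float(np.mean(s2f))
    else:
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8)
        d0 = 2 * half_d0
        s0 = math.exp(np.mean(e) + special.digamma(half_d0)
                      - math.log(half_d0))
    s2_post = (d0 * s0 + d * s2) / (d0 + d)
    t = (xb.mean(1) - xc.mean(1)) / np.sqrt(s2_post * (1 / nb + 1 / nc))
    df_total = min(d0 + d, len(s2) * d)
    return 2 * stats.t.sf(np.abs(t), df_total)


def logged_matrix(xb, xc):
    vals = np.hstack([xb, xc])
    df = pd.DataFrame(vals,
                      index=[f"p{i}" for i in range(vals.shape[0])],
                      columns=[f"bait_{j}" for j in range(xb.shape[1])]
                      + [f"control_{j}" for j in range(xc.shape[1])])
    design = {c: ("bait" if c.startswith("bait") else "control")
              for c in df.columns}
    return AbundanceMatrix(intensities=df, design=design, log_scale=True)


class TestModeratedT:
    def test_zero_shrinkage_reduces_to_pooled_t(self):
        rng = np.random.default_rng(5)
        xb = rng.normal(10, 1, size=(30, 3))
        xc = rng.normal(10, 1, size=(30, 3))
        recs = ia.moderated_t_test(logged_matrix(xb, xc), d0_override=0)
        ref = stats.ttest_ind(xb, xc, axis=1, equal_var=True)
        assert np.allclose([r.p_value for r in recs], ref.pvalue)
        assert np.allclose([r.t_statistic for r in recs], ref.statistic)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        # heteroscedastic: protein-specific sds drawn from a chi distribution
        sds = 0.2 + rng.chisquare(3, size=80) / 6
        xb = rng.normal(10, sds[:, None], size=(80, 3))
        xc = rng.normal(10, sds[:, None], size=(80, 3))
        xb[:10] += 2.0
        recs = ia.moderated_t_test(logged_matrix(xb, xc))
        assert np.allclose([r.p_value for r in recs],
                           moderated_p_oracle(xb, xc), rtol=1e-8)

    def test_shrinkage_interpolates_between_s2_and_prior(self):
        rng = np.random.default_rng(6)
        xb = rng.normal(10, 1, size=(50, 3))
        xc = rng.normal(10, 1, size=(50, 3))
        m = logged_matrix(xb, xc)
        d = 4
        s2 = np.array([np.var(np.concatenate([
            xb[i] - xb[i].mean(), xc[i] - xc[i].mean()]), ddof=0)
            * 6 / d for i in range(50)])
        d0, s0 = ia.estimate_variance_prior(s2, d)
        recs = ia.moderated_t_test(m)
        for i, r in enumerate(recs):
            s2_post = (d0 * s0 + d * s2[i]) / (d0 + d)
            se = math.sqrt(s2_post * (2 / 3))
            assert r.t_statistic == pytest.approx(r.log2fc / se, rel=1e-9)

    def test_log2fc_sign_convention_is_bait_minus_control(self):
        xb = np.full((1, 3), 12.0)
        xc = np.full((1, 3), 10.0)
        recs = ia.moderated_t_test(logged_matrix(xb, xc), d0_override=0)
        assert recs[0].log2fc == pytest.approx(2.0)

    def test_missing_values_are_rejected(self):
        m = logged_matrix(np.full((2, 3), 10.0), np.full((2, 3), 10.0))
        m.intensities.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ia.moderated_t_test(m)

    def test_raw_scale_matrix_rejected(self):
        m = logged_matrix(np.full((2, 3), 10.0), np.full((2, 3), 10.0))
        m.log_scale = False
        with pytest.raises(ValueError, match="log2"):
            ia.moderated_t_test(m)


class TestVariancePrior:
    def test_trigamma_inverse_round_trip(self):
        for y in [1e-5, 0.01, 0.5, 2.0, 50.0, 1e5]:
            x = ia._trigamma_inverse(y)
            assert special.polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_recovers_planted_prior(self):
        # variances drawn from s0^2 * d0 / chi2(d0): the moment fit should
        # recover d0 and s0^2 from a large sample
        rng = np.random.default_rng(7)
        d0_true, s0_true, d = 4.0, 0.25, 4
        prior_vars = s0_true * d0_true / rng.chisquare(d0_true, size=200_000)
        s2 = prior_vars * rng.chisquare(d, size=200_000) / d
        d0, s0 = ia.estimate_variance_prior(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.05)
        assert s0 == pytest.approx(s0_true, rel=0.05)

    def test_homoscedastic_data_gives_infinite_shrinkage(self):
        # log-variance spread below sampling expectation -> d0 capped, and
        # s0^2 equals the mean sample variance
        s2 = np.full(100, 0.5)
        d0, s0 = ia.estimate_variance_prior(s2, 4)
        assert d0 == ia.D0_CAP
        assert s0 == pytest.approx(0.5)


class TestSelectInteractors:
    def rec(self, pid, lfc, p, nqb=3, nqc=3):
        return ia.EnrichmentRecord(protein_id=pid, log2fc=lfc, p_value=p,
                                   n_quantified_bait=nqb,
                                   n_quantified_control=nqc)

    def test_joint_thresholds(self):
        records = [
            self.rec("hit", 1.5, 0.001),
            self.rec("low_fc", 0.9, 0.001),
            self.rec("weak_p", 1.5, 0.02),
            self.rec("boundary_fc", 1.0, 0.001),   # >= 1 passes
            self.rec("boundary_p", 1.5, 0.01),     # p < 0.01 strict: fails
            self.rec("depleted", -2.0, 0.001),
        ]
        selected = ia.select_interactors(records)
        assert selected == {"hit", "boundary_fc"}

    def test_invalidation_resets_p_and_deselects(self):
        records = [self.rec("ghost", 3.0, 1e-6, nqb=2, nqc=3),
                   self.rec("solid", 3.0, 1e-6, nqb=3, nqc=0)]
        selected = ia.select_interactors(records)
        assert selected == {"solid"}
        ghost = records[0]
        assert ghost.invalidated and not ghost.selected
        assert ghost.p_value == 1.0

    def test_invalidation_checks_the_more_abundant_condition(self):
        # negative log2FC would check the control count, but negative FC
        # never passes selection in the first place
        records = [self.rec("dep", -3.0, 1e-6, nqb=3, nqc=1)]
        assert ia.select_interactors(records) == set()
        assert not records[0].invalidated

    def test_bh_adjustment_matches_scipy(self):
        pvals = [0.001, 0.01, 0.02, 0.5, 0.9]
        records = [self.rec(f"p{i}", 2.0, p) for i, p in enumerate(pvals)]
        ia.select_interactors(records)
        expected = stats.false_discovery_control(pvals, method="bh")
        assert np.allclose([r.adjusted_p for r in records], expected)


class TestBaitNetwork:
    # Six pairwise shared-interactor counts among six baits, forming two
    # triangles bridged by nothing.
    SHARED = {("R443", "L323"): 6, ("R443", "R595"): 3, ("L323", "R595"): 15,
              ("L410", "R721"): 34, ("L410", "R252"): 13,
              ("R721", "R252"): 15}

    def interactor_sets(self):
        """Construct interactor sets realizing exactly the SHARED counts."""
        sets = {b: set() for b in
                ["R443", "L323", "R595", "L410", "R721", "R252"]}
        for (a, b), n in self.SHARED.items():
            for i in range(n):
                shared = f"prey_{a}_{b}_{i}"
                sets[a].add(shared)
                sets[b].add(shared)
        return sets

    def test_weight_formula(self):
        sets = {"A": {"x", "y", "B"}, "B": {"x", "A"}}
        g = ia.build_bait_network(sets)
        e = g.edges["A", "B"]
        assert e["Nc"] == 1    # shared interactor: only "x"
        assert e["Ndc"] == 2   # each bait detected in the other's pulldown
        assert e["weight"] == 1 + 10 * 2

    def test_zero_weight_pairs_get_no_edge(self):
        g = ia.build_bait_network({"A": {"x"}, "B": {"y"}})
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B"}

    def test_duplicate_bait_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            ia.build_bait_network({"A": set()}, baits=["A", "A"])

    def test_worked_example_weights(self):
        g = ia.build_bait_network(self.interactor_sets())
        for (a, b), n in self.SHARED.items():
            assert g.edges[a, b]["weight"] == n
        assert g.number_of_edges() == 6

    def test_worked_example_splits_into_two_communities(self):
        g = ia.build_bait_network(self.interactor_sets())
        comms = ia.detect_communities(g, seed=0)
        assert sorted(map(sorted, comms)) == [
            ["L323", "R443", "R595"], ["L410", "R252", "R721"]]

    def test_louvain_reaches_brute_force_optimal_modularity(self):
        # exhaustive check over all 203 partitions of the six baits
        g = ia.build_bait_network(self.interactor_sets())
        nodes = sorted(g.nodes)

        def partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for smaller in partitions(rest):
                for i, block in enumerate(smaller):
                    yield smaller[:i] + [block + [first]] + smaller[i + 1:]
                yield smaller + [[first]]

        best = max(
            nx.community.modularity(g, [set(b) for b in part],
                                    weight="weight")
            for part in partitions(nodes))
        achieved = nx.community.modularity(
            g, ia.detect_communities(g, seed=0), weight="weight")
        assert achieved == pytest.approx(best)

    def test_isolated_bait_is_its_own_community(self):
        g = ia.build_bait_network({"A": {"x"}, "B": {"x"}, "C": set()})
        comms = ia.detect_communities(g)
        assert {"C"} in comms


class TestGlobalNetwork:
    def test_edge_count_equals_total_interactors(self):
        inter = {"b1": ["x", "y"], "b2": ["y", "z", "w"]}
        g = ia.assemble_global_network(inter)
        assert g.number_of_edges() == 5

    def test_region_precedence_membrane_over_all(self):
        inter = {"b": ["x"]}
        g = ia.assemble_global_network(
            inter, membrane=["x"],
            region_labels={"x": ["nucleoid", "virion"]})
        assert g.nodes["x"]["region"] == "membrane"

    def test_region_precedence_nucleoid_over_virion(self):
        g = ia.assemble_global_network(
            {"b": ["x"]}, region_labels={"x": ["virion", "nucleoid"]})
        assert g.nodes["x"]["region"] == "nucleoid"

    def test_unlabeled_viral_prey_is_virion_unassigned(self):
        g = ia.assemble_global_network({"b": ["x"]})
        assert g.nodes["x"]["region"] == "virion_unassigned"

    def test_host_prey_gets_host_origin_and_region(self):
        g = ia.assemble_global_network({"b": ["hostP"]},
                                       host_proteins=["hostP"],
                                       region_labels={"hostP": "nucleoid"})
        assert g.nodes["hostP"]["origin"] == "host"
        assert g.nodes["hostP"]["region"] == "host"

    def test_bait_flag_and_expression_default(self):
        g = ia.assemble_global_network({"b": ["x"]},
                                       expression={"b": "GV2"})
        assert g.nodes["b"]["is_bait"] and not g.nodes["x"]["is_bait"]
        assert g.nodes["b"]["expression_cluster"] == "GV2"
        assert g.nodes["x"]["expression_cluster"] == "none"
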