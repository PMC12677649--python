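from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mts.contrasts import (
    bh_adjust,
    bray_curtis,
    correlation_screen,
    delta_table,
    functional_summary,
    group_tests,
    shannon,
    volcano_enrichment,
    wilcoxon_rank_sum,
)
from mts.core_io import MtsError

from conftest import make_survey


class TestShannon:
    def test_uniform_and_point_mass(self):
        assert shannon(np.full(4, 0.25)) == pytest.approx(np.log(4))
        assert shannon(np.array([1.0, 0.0, 0.0])) == pytest.approx(0.0)

    def test_zero_taxa_do_not_contribute(self):
        a = shannon(np.array([0.5, 0.5, 0.0, 0.0]))
        b = shannon(np.array([0.5, 0.5, 0.0]))
        assert a == pytest.approx(b)

    def test_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            assert shannon(p) <= np.log(6) + 1e-12

    def test_negative_abundance_rejected(self):
        with pytest.raises(MtsError):
            shannon(np.array([0.5, -0.1, 0.6]))


class TestBrayCurtis:
    def test_identity_disjoint_symmetry(self):
        x = np.array([0.2, 0.8, 0.0])
        y = np.array([0.0, 0.0, 1.0])
        assert bray_curtis(x, x) == pytest.approx(0.0)
        assert bray_curtis(x, y) == pytest.approx(1.0)
        assert bray_curtis(x, y) == pytest.approx(bray_curtis(y, x))

    def test_both_zero_rejected(self):
        with pytest.raises(MtsError):
            bray_curtis(np.zeros(3), np.zeros(3))


class TestDeltaTable:
    def survey_with(self, of_values, gh_values, var="NH4"):
        survey = make_survey(
            {"of1": [1, 1], "gh1": [1, 1], "of2": [1, 1], "gh2": [1, 1]},
            meta={"site_id": ["a", "a", "b", "b"],
                  "system": ["OF", "GH", "OF", "GH"]},
        )
        survey.meta.loc[["of1", "of2"], var] = of_values
        survey.meta.loc[["gh1", "gh2"], var] = gh_values
        return survey

    def test_log10_ratio(self):
        survey = self.survey_with([100.0, 50.0], [200.0, 50.0])
        deltas = delta_table(survey)
        assert deltas.loc["gh1", "NH4"] == pytest.approx(np.log10(2.0))
        assert deltas.loc["gh2", "NH4"] == pytest.approx(0.0)

    def test_delta_npk_mean_of_equal_ratios(self):
        survey = make_survey(
            {"of": [1, 1], "gh": [1, 1]},
            meta={"site_id": ["a", "a"], "system": ["OF", "GH"]},
        )
        for var in ("NH4", "NO3", "AP", "AK"):
            survey.meta.loc["of", var] = 10.0
            survey.meta.loc["gh", var] = 20.0
        deltas = delta_table(survey)
        assert deltas.loc["gh", "delta_NPK"] == pytest.approx(np.log10(2.0))

    def test_zero_member_dropped_with_nan(self):
        survey = self.survey_with([0.0, 50.0], [200.0, 100.0])
        deltas = delta_table(survey)
        assert np.isnan(deltas.loc["gh1", "NH4"])
        assert deltas.loc["gh2", "NH4"] == pytest.approx(np.log10(2.0))

    def test_antisymmetric_under_system_swap(self):
        survey = self.survey_with([100.0, 50.0], [200.0, 25.0])
        swapped = make_survey(
            {s: survey.abundance.loc[s] for s in survey.samples},
            meta={"site_id": list(survey.meta["site_id"]),
                  "system": ["GH", "OF", "GH", "OF"]},
        )
        for var in survey.meta.columns:
            if var not in ("site_id", "system"):
                swapped.meta[var] = survey.meta[var]
        d1 = delta_table(survey).sort_values("site_id")
        d2 = delta_table(swapped).sort_values("site_id")
        num = [c for c in d1.columns if c not in ("site_id", "of_sample")]
        assert np.allclose(d1[num].to_numpy(), -d2[num].to_numpy(), equal_nan=True)


class TestWilcoxon:
    def test_extreme_arrangement_exact_p(self):
        w, p = wilcoxon_rank_sum(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1)
        assert w == 6.0  # ranks 1+2+3

    def test_identical_multisets_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p = wilcoxon_rank_sum(x, x)
        assert p == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(1, 1, size=9)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 5), (6, 6)])
    def test_matches_enumeration_oracle(self, nx, ny):
        """Exact two-sided p equals full enumeration over rank splits."""
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(10):
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = pooled[:nx], pooled[nx:]
            _, p = wilcoxon_rank_sum(x, y)
            # oracle: enumerate all C(nx+ny, nx) assignments of ranks to x
            ranks = np.argsort(np.argsort(np.concatenate([x, y]))) + 1
            w_obs = ranks[:nx].sum()
            mean_w = nx * (nx + ny + 1) / 2
            stats_all = [sum(c) for c in combinations(range(1, nx + ny + 1), nx)]
            extreme = sum(abs(s - mean_w) >= abs(w_obs - mean_w) - 1e-9 for s in stats_all)
            assert p == pytest.approx(extreme / len(stats_all))

    def test_empty_sample_rejected(self):
        with pytest.raises(MtsError):
            wilcoxon_rank_sum(np.array([]), np.array([1.0]))


class TestBH:
    def test_step_up_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.42]))[0] == pytest.approx(0.42)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=20)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=15))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rejection_set_matches_brute_force(self, p_list):
        """BH q < alpha iff the step-up rule rejects at alpha."""
        alpha = 0.05
        p = np.array(p_list)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * alpha / m:
                k_max = rank
        rejected_brute = np.zeros(m, bool)
        rejected_brute[order[:k_max]] = True
        assert np.array_equal(q <= alpha, rejected_brute) or np.allclose(
            np.sort(q[q <= alpha]), np.sort(q[rejected_brute]))

    def test_out_of_range_rejected(self):
        with pytest.raises(MtsError):
            bh_adjust(np.array([0.5, 1.5]))


class TestVolcano:
    def toy(self, lfc_q_pairs):
        """Build a feature table whose group means and p-values land on the
        requested (log2 fc, q) grid only approximately; instead test the
        threshold logic directly through constructed means."""
        rng = np.random.default_rng(0)
        n = 20
        features = {}
        systems = ["OF"] * n + ["GH"] * n
        for i, (lfc, q_small) in enumerate(lfc_q_pairs):
            of_mean = 10.0
            gh_mean = of_mean * 2.0**lfc
            of_vals = rng.normal(of_mean, 0.01, n).clip(min=0.01)
            if q_small:
                gh_vals = rng.normal(gh_mean, 0.01, n).clip(min=0.01)
            else:
                # mean shifted by one huge outlier, ranks barely move -> large p
                gh_vals = rng.normal(of_mean, 0.01, n).clip(min=0.01)
                gh_vals[0] = gh_mean * n
            features[f"f{i}"] = np.concatenate([of_vals, gh_vals])
        table = pd.DataFrame(features, index=[f"s{i}" for i in range(2 * n)])
        system = pd.Series(systems, index=table.index)
        return table, system

    def test_threshold_partition(self):
        table, system = self.toy([
            (1.5, True), (-2.0, True), (0.5, True), (3.0, False), (-1.2, True),
        ])
        out = volcano_enrichment(table, system).set_index("feature")
        assert out.loc["f0", "enriched_in"] == "GH"
        assert out.loc["f1", "enriched_in"] == "OF"
        assert out.loc["f2", "enriched_in"] == "neither"  # |lfc| below threshold
        assert out.loc["f3", "enriched_in"] == "neither"  # q above threshold
        assert out.loc["f4", "enriched_in"] == "OF"
        assert (out["enriched_in"] == "GH").sum() == 1
        assert (out["enriched_in"] == "OF").sum() == 2

    def test_label_flip_swaps_sets(self):
        table, system = self.toy([(2.0, True), (-2.0, True), (0.0, True)])
        out1 = volcano_enrichment(table, system).set_index("feature")["enriched_in"]
        flipped = system.map({"OF": "GH", "GH": "OF"})
        out2 = volcano_enrichment(table, flipped).set_index("feature")["enriched_in"]
        swap = {"GH": "OF", "OF": "GH", "neither": "neither"}
        assert (out1.map(swap) == out2).all()

    def test_all_q_one_no_enrichment(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.uniform(5, 6, size=(20, 5)),
                             columns=[f"f{i}" for i in range(5)])
        system = pd.Series(["OF"] * 10 + ["GH"] * 10, index=table.index)
        out = volcano_enrichment(table, system)
        assert (out["enriched_in"] == "neither").all()


class TestFunctionalSummary:
    def test_fraction_and_richness(self):
        genes = pd.DataFrame({"ko": ["KO1", "KO1", ""], "abundance": [2.0, 3.0, 5.0]})
        fraction, richness = functional_summary(genes)
        assert fraction == pytest.approx(0.5)
        assert richness == 1

    def test_all_unlabeled(self):
        genes = pd.DataFrame({"ko": ["", ""], "abundance": [1.0, 2.0]})
        assert functional_summary(genes) == (0.0, 0)

    def test_row_duplication_invariance(self):
        genes = pd.DataFrame({"ko": ["KO1", "KO2", ""], "abundance": [1.0, 2.0, 3.0]})
        doubled = pd.concat([genes, genes], ignore_index=True)
        assert functional_summary(genes) == functional_summary(doubled)

    def test_empty_rejected(self):
        with pytest.raises(MtsError):
            functional_summary(pd.DataFrame({"ko": [], "abundance": []}))


class TestCorrelationScreen:
    def test_linear_and_monotone(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        y = pd.DataFrame({"lin": 2 * np.arange(10.0) + 1, "cube": np.arange(10.0) ** 3})
        pearson = correlation_screen(y, x, method="pearson").set_index("feature")
        spearman = correlation_screen(y, x, method="spearman").set_index("feature")
        assert pearson.loc["lin", "r"] == pytest.approx(1.0)
        assert spearman.loc["cube", "r"] == pytest.approx(1.0)
        assert pearson.loc["cube", "r"] < 1.0

    def test_zero_variance_gives_na(self):
        x = pd.DataFrame({"x": np.arange(6.0)})
        y = pd.DataFrame({"const": np.full(6, 3.0)})
        out = correlation_screen(y, x)
        assert np.isnan(out["r"].iloc[0])


class TestGroupTests:
    def test_direction_and_percent_difference(self, paired_survey):
        values = pd.DataFrame(
            {"v": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0]}, index=paired_survey.samples)
        out = group_tests(values, paired_survey.meta["system"]).iloc[0]
        assert out["direction"] == "GH"
        assert out["percent_difference"] == pytest.approx(100.0)
        assert out["q"] >= out["p"]
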