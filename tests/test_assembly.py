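import numpy as np
import pandas as pd
import pytest

from mts.assembly import (
    DDRFit,
    beta_mntd,
    beta_nti,
    ddr,
    ddr_slope_difference,
    fit_ncm,
    haversine_km,
    ncm_predicted_frequency,
    permanova,
    raup_crick_bray,
)
from mts.contrasts import bray_curtis_matrix
from mts.core_io import MtsError, tree_distance_matrix
from mts.synthetic import simulate_assembly, simulate_tree

from conftest import make_survey, random_sparse_survey
import dendropy


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


class TestBetaMNTD:
    def test_hand_worked_two_by_two(self):
        """Four-taxon toy with known nearest-taxon distances gives 0.15."""
        # place A,B,C,D so that d(A,C)=0.2, d(A,D)=0.6, d(B,C)=0.4, d(B,D)=0.1
        # via explicit branch lengths on a ladder tree
        newick = "((A:0.05,C:0.15):0.2,(B:0.05,D:0.05):0.0):0.0;"
        tree = tree_from_newick(newick)
        taxa = ["A", "B", "C", "D"]
        d = tree_distance_matrix(tree, taxa)
        # verify the constructed distances before using them
        assert d[0, 2] == pytest.approx(0.2)
        assert d[1, 3] == pytest.approx(0.1)
        survey = make_survey({"k": [0.5, 0.5, 0.0, 0.0], "m": [0.0, 0.0, 0.5, 0.5]})
        survey.abundance.columns = taxa
        value = beta_mntd(survey, tree, pair=("k", "m"))
        expected = 0.5 * (0.5 * d[0, 2:].min() + 0.5 * d[1, 2:].min()
                          + 0.5 * d[2, :2].min() + 0.5 * d[3, :2].min())
        assert value == pytest.approx(expected)

    def test_identical_communities_zero(self):
        tree = simulate_tree(6, seed=0, labels=list("ABCDEF"))
        survey = make_survey({"k": [1, 2, 3, 0, 0, 0], "m": [1, 2, 3, 0, 0, 0]})
        survey.abundance.columns = list("ABCDEF")
        assert beta_mntd(survey, tree, pair=("k", "m")) == pytest.approx(0.0)

    def test_linear_in_branch_lengths(self):
        t1 = simulate_tree(8, seed=3)
        t2 = t1.clone(depth=1)
        for edge in t2.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 2
        taxa = sorted(l.taxon.label for l in t1.leaf_node_iter())
        survey = random_sparse_survey(4, 8, seed=1)
        survey.abundance.columns = taxa
        m1 = beta_mntd(survey, t1)
        m2 = beta_mntd(survey, t2)
        assert np.allclose(2 * m1.to_numpy(), m2.to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        """Vectorized βMNTD equals a naive per-taxon double loop."""
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(4, 10))
        tree = simulate_tree(n_taxa, seed=seed + 10)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        survey = random_sparse_survey(4, n_taxa, seed=seed, depth=30)
        survey.abundance.columns = taxa
        d = tree_distance_matrix(tree, taxa)
        p = survey.abundance.to_numpy()
        mat = beta_mntd(survey, tree).to_numpy()
        for k in range(4):
            for m in range(4):
                if k == m:
                    continue
                total = 0.0
                for i in range(n_taxa):
                    if p[k, i] > 0:
                        total += 0.5 * p[k, i] * min(d[i, j] for j in range(n_taxa) if p[m, j] > 0)
                for j in range(n_taxa):
                    if p[m, j] > 0:
                        total += 0.5 * p[m, j] * min(d[j, i] for i in range(n_taxa) if p[k, i] > 0)
                assert mat[k, m] == pytest.approx(total, abs=1e-12)


class TestBetaNTI:
    def test_neutral_data_mostly_stochastic(self):
        tree = simulate_tree(100, seed=5)
        survey = simulate_assembly("neutral", tree, N=1000, m=0.1, n_samples=12, seed=7)
        result = beta_nti(survey, tree, n_null=199, seed=1)
        vals = result.bnti.to_numpy()[np.triu_indices(12, 1)]
        assert np.mean(np.abs(vals[~np.isnan(vals)]) < 2) >= 0.9

    def test_selection_data_exceeds_threshold(self):
        tree = simulate_tree(100, seed=5)
        survey = simulate_assembly("selection", tree, n_samples=12, seed=8)
        result = beta_nti(survey, tree, n_null=199, seed=1)
        vals = result.bnti.to_numpy()[np.triu_indices(12, 1)]
        assert np.nanmedian(np.abs(vals)) > 2

    def test_reproducible_under_seed(self):
        tree = simulate_tree(30, seed=2)
        survey = simulate_assembly("neutral", tree, n_samples=5, seed=3)
        a = beta_nti(survey, tree, n_null=49, seed=9).bnti
        b = beta_nti(survey, tree, n_null=49, seed=9).bnti
        pd.testing.assert_frame_equal(a, b)

    def test_single_sample_rejected(self):
        tree = simulate_tree(10, seed=0)
        survey = simulate_assembly("neutral", tree, n_samples=3, seed=1)
        with pytest.raises(MtsError):
            beta_nti(survey.subset(survey.samples[:1]), tree, n_null=9)


class TestRaupCrick:
    def test_identical_communities_hit_lower_bound(self):
        """Identical sparse communities: observed BC = 0 beats every null
        (no null draw reproduces both communities exactly)."""
        rng = np.random.default_rng(0)
        shared = rng.multinomial(400, rng.dirichlet(np.ones(6)), size=1)[0]
        rows = {"a": np.concatenate([shared, np.zeros(9)]),
                "b": np.concatenate([shared, np.zeros(9)])}
        for i in range(4):
            rows[f"c{i}"] = rng.multinomial(400, rng.dirichlet(np.ones(15)))
        survey = make_survey(rows)
        rc = raup_crick_bray(survey, pair=("a", "b"), n_null=99, seed=0)
        assert rc == pytest.approx(-1.0)

    def test_symmetric_in_pair_order(self):
        survey = random_sparse_survey(4, 10, seed=2, depth=50)
        ab = raup_crick_bray(survey, pair=(survey.samples[0], survey.samples[1]),
                             n_null=99, seed=5)
        ba = raup_crick_bray(survey, pair=(survey.samples[1], survey.samples[0]),
                             n_null=99, seed=5)
        assert ab == pytest.approx(ba)

    def test_bounded_in_unit_interval(self):
        survey = random_sparse_survey(5, 12, seed=3, depth=80)
        mat = raup_crick_bray(survey, n_null=49, seed=1)
        vals = mat.to_numpy()[np.triu_indices(5, 1)]
        assert np.all(vals >= -1.0) and np.all(vals <= 1.0)

    def test_null_typical_pair_near_zero(self):
        """A community drawn from the null recipe itself sits near RC = 0."""
        rng = np.random.default_rng(11)
        regional = rng.dirichlet(np.ones(30))
        counts = {f"s{i}": rng.multinomial(300, regional) for i in range(12)}
        survey = make_survey(counts)
        rcs = [raup_crick_bray(survey, pair=(f"s{2*i}", f"s{2*i+1}"), n_null=199, seed=i)
               for i in range(6)]
        assert abs(np.mean(rcs)) < 0.35


class TestNCM:
    @staticmethod
    def survey_with_frequencies(p_bar: np.ndarray, freq: np.ndarray, n_samples: int):
        """Survey whose taxa hit given occurrence frequencies and regional
        means: taxon t occurs in round(freq·n) samples at a constant value
        chosen so its regional mean is p_bar[t]; a filler taxon absorbs the
        per-row remainder."""
        n_taxa = len(p_bar)
        k = np.maximum(np.rint(freq * n_samples).astype(int), 1)
        v = p_bar * n_samples / k
        rows = np.zeros((n_samples, n_taxa + 1))
        for t in range(n_taxa):
            rows[:k[t], t] = v[t]
        rows[:, -1] = 1.0 - rows[:, :-1].sum(axis=1)
        assert (rows[:, -1] > 0).all()
        return make_survey({f"s{i}": rows[i] for i in range(n_samples)})

    def test_perfect_curve_r2_one(self):
        """Frequencies placed exactly on the Sloan curve give R² ≈ 1."""
        rng = np.random.default_rng(4)
        n_taxa, N, m, n_samples = 40, 1000.0, 0.15, 200
        p_bar = rng.uniform(5e-4, 5e-3, n_taxa)
        freq = ncm_predicted_frequency(p_bar, N, m, 1.0 / N)
        survey = self.survey_with_frequencies(p_bar, freq, n_samples)
        fit = fit_ncm(survey, N=N)
        assert fit.r_squared > 0.99
        assert abs(fit.m - m) / m < 0.1

    def test_recovers_migration_from_sloan_data(self):
        tree = simulate_tree(300, seed=6)
        survey = simulate_assembly("neutral", tree, N=1000, m=0.1, n_samples=50, seed=9)
        fit = fit_ncm(survey, N=1000)
        assert abs(fit.m - 0.1) / 0.1 < 0.2

    def test_predicted_frequency_monotone_in_pbar(self):
        p_bar = np.linspace(1e-4, 0.2, 100)
        pred = ncm_predicted_frequency(p_bar, 1000.0, 0.1, 1e-3)
        assert np.all(np.diff(pred) >= -1e-12)

    def test_noise_fits_worse_than_neutral(self):
        """Occurrence frequencies decoupled from regional abundance fit
        substantially worse than on-curve frequencies."""
        rng = np.random.default_rng(7)
        n_taxa, N, m, n_samples = 40, 1000.0, 0.15, 200
        p_bar = rng.uniform(5e-4, 5e-3, n_taxa)
        on_curve = ncm_predicted_frequency(p_bar, N, m, 1.0 / N)
        noise_freq = rng.uniform(0.05, 0.95, n_taxa)  # independent of p_bar
        fit_good = fit_ncm(self.survey_with_frequencies(p_bar, on_curve, n_samples), N=N)
        fit_bad = fit_ncm(self.survey_with_frequencies(p_bar, noise_freq, n_samples), N=N)
        assert fit_good.r_squared > fit_bad.r_squared + 0.3


class TestDDR:
    def test_exact_line_recovered(self):
        """Pairs lying exactly on S = 0.8 - 0.01 D fit perfectly."""
        rng = np.random.default_rng(0)
        points = pd.DataFrame({"distance": rng.uniform(0, 50, 40)})
        points["similarity"] = 0.8 - 0.01 * points["distance"]
        from scipy import stats as sps

        res = sps.linregress(points["distance"], points["similarity"])
        assert res.slope == pytest.approx(-0.01)
        # and through the survey interface with synthetic coordinates:
        survey = random_sparse_survey(8, 20, seed=1, depth=200)
        fit = ddr(survey, kind="geographic")
        assert fit.points.shape[0] == 8 * 7 // 2

    def test_colocated_samples_rejected(self):
        survey = random_sparse_survey(4, 10, seed=2)
        survey.meta["latitude"] = 30.0
        survey.meta["longitude"] = 110.0
        with pytest.raises(MtsError, match="variance"):
            ddr(survey, kind="geographic")

    def test_sample_order_invariance(self):
        survey = random_sparse_survey(6, 15, seed=3)
        fit1 = ddr(survey, kind="edaphic")
        perm = [survey.samples[i] for i in (3, 1, 5, 0, 4, 2)]
        fit2 = ddr(survey.subset(perm), kind="edaphic")
        assert fit1.slope == pytest.approx(fit2.slope)
        assert fit1.r_squared == pytest.approx(fit2.r_squared)

    def test_haversine_known_distance(self):
        # one degree of latitude is ~111.2 km
        d = haversine_km(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert d[0, 1] == pytest.approx(111.19, abs=0.1)


class TestSlopeDifference:
    def line_fit(self, slope, noise_sd, n, seed, group):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, n)
        y = 0.9 + slope * x + rng.normal(0, noise_sd, n)
        from scipy import stats as sps

        res = sps.linregress(x, y)
        return DDRFit(slope=float(res.slope), intercept=float(res.intercept),
                      r_squared=float(res.rvalue**2), group=group, kind="geographic",
                      points=pd.DataFrame({"distance": x, "similarity": y}))

    def test_zero_observed_difference_p_one(self):
        fit = self.line_fit(-0.01, 0.0, 30, 0, "a")
        assert ddr_slope_difference(fit, fit, n_perm=199, seed=0) == 1.0

    def test_detects_clear_slope_difference(self):
        a = self.line_fit(-0.02, 0.001, 40, 1, "OF")
        b = self.line_fit(-0.002, 0.001, 40, 2, "GH")
        assert ddr_slope_difference(a, b, n_perm=999, seed=3) <= 0.01

    def test_seeded_reproducibility(self):
        a = self.line_fit(-0.02, 0.05, 30, 4, "OF")
        b = self.line_fit(-0.015, 0.05, 30, 5, "GH")
        p1 = ddr_slope_difference(a, b, n_perm=199, seed=6)
        p2 = ddr_slope_difference(a, b, n_perm=199, seed=6)
        assert p1 == p2 and p1 > 0


class TestPermanova:
    def two_cluster_survey(self):
        rng = np.random.default_rng(8)
        rows = {}
        systems = []
        for i in range(10):
            rows[f"o{i}"] = np.concatenate([rng.dirichlet(np.ones(5) * 5), np.zeros(5)])
            systems.append("OF")
        for i in range(10):
            rows[f"g{i}"] = np.concatenate([np.zeros(5), rng.dirichlet(np.ones(5) * 5)])
            systems.append("GH")
        return make_survey(rows, meta={"system": systems})

    def test_separated_clusters_minimal_p(self):
        """Disjoint-support clusters: every permutation that changes the
        partition scores lower, so p is at (or within one tied, partition-
        preserving draw of) the smallest attainable value 1/(n_perm+1)."""
        survey = self.two_cluster_survey()
        bc = bray_curtis_matrix(survey)
        f, p = permanova(bc, survey.meta["system"], n_perm=999, seed=0)
        assert p <= 2 / 1000
        assert f > 10

    def test_relabel_invariance_of_f(self):
        survey = self.two_cluster_survey()
        bc = bray_curtis_matrix(survey)
        f1, _ = permanova(bc, survey.meta["system"], n_perm=49, seed=0)
        flipped = survey.meta["system"].map({"OF": "GH", "GH": "OF"})
        f2, _ = permanova(bc, flipped, n_perm=49, seed=0)
        assert f1 == pytest.approx(f2)

    def test_matches_skbio(self):
        """Pseudo-F agrees with the independent scikit-bio implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova, DistanceMatrix

        survey = random_sparse_survey(12, 10, seed=9, depth=100)
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=survey.samples)
        bc = bray_curtis_matrix(survey)
        f, _ = permanova(bc, labels, n_perm=9, seed=0)
        sk = sk_permanova(DistanceMatrix(bc.to_numpy(), ids=survey.samples),
                          grouping=labels.to_list(), permutations=9)
        assert f == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_singleton_group_rejected(self):
        survey = random_sparse_survey(5, 8, seed=1)
        labels = pd.Series(["A"] * 4 + ["B"], index=survey.samples)
        bc = bray_curtis_matrix(survey)
        with pytest.raises(MtsError, match="singleton"):
            permanova(bc, labels)
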