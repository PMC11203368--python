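"""Hallmark set algebra, Cox TTF screen, 2x2 tests, enrichment and clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cfhallmarks import hallmarks as hm
from cfhallmarks import synthdata
from cfhallmarks.hallmarks import DMRSet, HallmarkSet


def dmr_set(name, ids, lfc=1.0):
    return DMRSet(name=name, contrast=f"{name} vs HBD",
                  log2fc={i: lfc for i in ids})


UNIVERSE = [f"e{i}" for i in range(10)]
subsets = st.sets(st.sampled_from(UNIVERSE), max_size=10)


class TestSetAlgebra:
    def test_worked_example(self):
        a, b = dmr_set("a", {"1", "2", "3"}), dmr_set("b", {"2", "3", "4"})
        ua, ub, shared = hm.unique_and_shared(a, b)
        assert (ua, ub, shared) == ({"1"}, {"4"}, {"2", "3"})

    def test_identical_sets_share_everything(self):
        a = dmr_set("a", {"1", "2"})
        ua, ub, shared = hm.unique_and_shared(a, a)
        assert ua == ub == set() and shared == {"1", "2"}

    @given(subsets, subsets)
    @settings(max_examples=500, derandomize=True, deadline=None)
    def test_partition_property(self, ids_a, ids_b):
        a, b = dmr_set("a", ids_a), dmr_set("b", ids_b)
        ua, ub, shared = hm.unique_and_shared(a, b)
        assert ua | ub | shared == ids_a | ids_b
        assert not (ua & ub or ua & shared or ub & shared)

    def test_tissue_restrict_intersection(self):
        tissue = dmr_set("tissue", {"b", "c", "d"})
        assert hm.tissue_restrict({"a", "b", "c"}, tissue) == {"b", "c"}

    def test_tissue_restrict_disjoint_warns_empty(self):
        tissue = dmr_set("tissue", {"x"})
        with pytest.warns(UserWarning, match="tissue"):
            assert hm.tissue_restrict({"a", "b"}, tissue) == set()

    def test_tissue_restrict_subset_unchanged(self):
        tissue = dmr_set("tissue", {"a", "b", "c"})
        assert hm.tissue_restrict({"a", "b"}, tissue) == {"a", "b"}


class TestDefineHallmarks:
    def make_subsets(self):
        # planted structure: pre-unique {p1,p2}, post-unique {q1}, shared {s}
        tissue_ids = {"p1", "q1", "r1", "s", "t1", "u1"}
        return {
            "pre": dmr_set("pre", {"p1", "p2", "s"}),
            "post": dmr_set("post", {"q1", "s"}),
            "preR": dmr_set("preR", {"r1", "r2", "s"}),
            "preS": dmr_set("preS", {"t1", "s"}),
            "postR": dmr_set("postR", {"u1", "s"}),
            "postS": dmr_set("postS", {"v1", "s"}),
            "tissue": dmr_set("tissue", tissue_ids),
        }

    def test_planted_truth_recovered(self):
        marks = hm.define_hallmarks(self.make_subsets())
        # unique sides intersected with tissue: p2, r2, v1 drop out
        assert marks["DTE"].region_ids == {"p1", "q1"}
        assert marks["PP"].region_ids == {"r1", "t1"}
        assert marks["PR"].region_ids == {"u1"}
        assert marks["DTE"].provenance == {"p1": "pre-unique",
                                           "q1": "post-unique"}
        assert marks["PP"].provenance["r1"] == "preR-unique"

    def test_identical_subsets_give_empty_hallmarks(self):
        s = dmr_set("x", {"a", "b"})
        subsets = {k: s for k in hm.REQUIRED_SUBSETS}
        marks = hm.define_hallmarks(subsets)
        assert all(len(m) == 0 for m in marks.values())

    def test_missing_subset_named(self):
        subsets = self.make_subsets()
        del subsets["postR"]
        with pytest.raises(ValueError, match="postR"):
            hm.define_hallmarks(subsets)

    def test_size_equals_sum_of_provenance_sides(self):
        # e.g. resistant-unique 274 + sensitive-unique 30 compose a 304-DMR set
        marks = hm.define_hallmarks(self.make_subsets())
        for m in marks.values():
            assert len(m) == sum(m.side_counts().values())
        assert 274 + 30 == 304  # the printed PP composition is consistent

    def test_overlap_report_partitions_union(self):
        marks = hm.define_hallmarks(self.make_subsets())
        overlap = hm.hallmark_overlap(marks)
        union = set().union(*(m.region_ids for m in marks.values()))
        only = sum(v for k, v in overlap.items() if k.endswith("_only"))
        assert only <= len(union)


def _breslow_loglik(beta, x, t, d):
    """Independent partial-likelihood oracle (vectorized over a beta grid)."""
    order = np.argsort(t, kind="stable")
    x, t, d = x[order], t[order], d[order]
    beta = np.atleast_1d(beta)
    w = np.exp(np.outer(beta, x))  # B x n
    s0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    return (d * (np.outer(beta, x) - np.log(s0))).sum(axis=1)


class TestCox:
    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        t = rng.exponential(1, size=10)
        fit = hm.cox_ttf(x, t)
        grid = np.arange(-3, 3, 1e-4)
        ll = _breslow_loglik(grid, x, t, np.ones(10))
        assert fit.log_hr == pytest.approx(grid[np.argmax(ll)], abs=1e-3)

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        df = synthdata.gen_survival(60, x, log_hr=0.5, seed=6)
        fit = hm.cox_ttf(df["covariate"], df["time"], df["event"])
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        assert fit.log_hr == pytest.approx(cph.params_["covariate"], abs=1e-4)
        assert fit.se == pytest.approx(
            cph.standard_errors_["covariate"], abs=1e-4
        )

    def test_loghr_recovery(self):
        # planted log HR = log 2 on a binary covariate, n=200, 100 sims
        x = np.repeat([0.0, 1.0], 100)
        estimates = [
            hm.cox_ttf(x, synthdata.gen_survival(
                200, x, log_hr=np.log(2), seed=s)["time"]).log_hr
            for s in range(100)
        ]
        assert abs(np.mean(estimates) - np.log(2)) <= 0.1

    def test_null_type_I_error(self):
        # covariate independent of survival: ~5% of Wald p-values below 0.05
        rng = np.random.default_rng(7)
        pvals = []
        for s in range(1000):
            x = rng.normal(size=50)
            t = rng.exponential(1, size=50)
            pvals.append(hm.cox_ttf(x, t).p)
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_affine_rescaling_of_covariate(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        t = rng.exponential(1, size=40)
        base = hm.cox_ttf(x, t)
        scaled = hm.cox_ttf(3.0 * x + 7.0, t)
        assert scaled.log_hr == pytest.approx(base.log_hr / 3.0, rel=1e-6)
        assert scaled.p == pytest.approx(base.p, rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            hm.cox_ttf(np.ones(12), np.arange(1, 13))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="10"):
            hm.cox_ttf(np.arange(5), np.arange(1, 6))


class TestChi2:
    @pytest.mark.parametrize(
        "table,expected_p",
        [([[9, 12], [6, 4]], 0.372),      # FIGO stage
         ([[10, 12], [3, 3]], 0.843),     # surgical outcome
         ([[14, 14], [1, 2]], 0.583)],    # previous chemotherapy lines
    )
    def test_printed_cohort_tables(self, table, expected_p):
        _, p = hm.chi2_2x2(table)
        assert round(p, 3) == expected_p

    def test_balanced_table_is_null(self):
        chi2, p = hm.chi2_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            hm.chi2_2x2([[0, 0], [5, 5]])

    def test_matches_scipy_uncorrected(self, rng):
        for _ in range(50):
            tab = rng.integers(1, 40, (2, 2))
            chi2, p = hm.chi2_2x2(tab)
            ref = stats.chi2_contingency(tab, correction=False)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_yates_correction_matches_scipy(self, rng):
        for _ in range(20):
            tab = rng.integers(1, 40, (2, 2))
            chi2, p = hm.chi2_2x2(tab, correction=True)
            ref = stats.chi2_contingency(tab, correction=True)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-12)

    @pytest.mark.parametrize("table", [[[45, 62], [66, 34]],
                                       [[30, 70], [55, 45]],
                                       [[125, 75], [100, 110]]])
    def test_matches_permutation_oracle(self, table):
        # conditional null with fixed margins: a ~ hypergeometric
        tab = np.asarray(table)
        chi2_obs, p = hm.chi2_2x2(tab)
        n = tab.sum()
        r1, c1 = tab[0].sum(), tab[:, 0].sum()
        rng = np.random.default_rng(42)
        a = rng.hypergeometric(c1, n - c1, r1, size=100_000)
        b, c = r1 - a, c1 - a
        d = n - r1 - c1 + a
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2_perm = n * (a * d - b * c) ** 2 / (
                r1 * (n - r1) * c1 * (n - c1)
            )
        p_mc = (chi2_perm >= chi2_obs - 1e-9).mean()
        se = math.sqrt(p_mc * (1 - p_mc) / 100_000)
        # chi-square df=1 approximates the exact conditional null at these
        # cell sizes; small residual discreteness remains beyond the MC error
        assert abs(p - p_mc) <= 3 * se + 0.01


def _fisher_oracle(table):
    """Exhaustive enumeration with math.comb, independent of scipy."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c

    def prob(aa):
        return (math.comb(c1, aa) * math.comb(n - c1, r1 - aa)
                / math.comb(n, r1))

    p_obs = prob(a)
    return sum(
        prob(aa)
        for aa in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if prob(aa) <= p_obs * (1 + 1e-7)
    )


class TestFisher:
    def test_symmetric_2x2_is_one(self):
        assert hm.fisher_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_worked_sparse_table(self):
        table = [[0, 14], [4, 12]]
        assert hm.fisher_2x2(table) == pytest.approx(_fisher_oracle(table),
                                                     abs=1e-10)

    def test_matches_enumeration_for_all_small_margins(self):
        # all tables with total <= 30 over a margin grid
        for r1, c1, n in [(5, 5, 10), (14, 16, 30), (7, 12, 25), (10, 3, 20)]:
            for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                tab = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                assert hm.fisher_2x2(tab) == pytest.approx(
                    _fisher_oracle(tab), abs=1e-9
                )

    def test_matches_scipy(self, rng):
        for _ in range(30):
            tab = rng.integers(0, 15, (2, 2))
            if tab.sum() == 0:
                continue
            assert hm.fisher_2x2(tab) == pytest.approx(
                stats.fisher_exact(tab).pvalue, abs=1e-9
            )


class TestEnrichment:
    def test_disjoint_term(self):
        out = hm.enrich({"g1", "g2"}, {"T": {"g8", "g9"}},
                        {f"g{i}" for i in range(10)})
        row = out.iloc[0]
        assert row["k"] == 0 and row["p"] == 1.0
        assert row["enrichment_factor"] == 0.0

    def test_direct_hypergeometric_value(self):
        background = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)}  # all 5 inside the term
        out = hm.enrich(query, {"T": term}, background)
        expected = sum(
            math.comb(10, i) * math.comb(90, 5 - i) / math.comb(100, 5)
            for i in range(5, 6)
        )
        assert out.iloc[0]["p"] == pytest.approx(expected, rel=1e-9)
        assert out.iloc[0]["enrichment_factor"] == pytest.approx(10.0)

    def test_saturated_term(self):
        background = {f"g{i}" for i in range(20)}
        out = hm.enrich({"g0", "g1"}, {"ALL": set(background)}, background)
        assert out.iloc[0]["enrichment_factor"] == pytest.approx(1.0)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_p_monotone_in_overlap(self):
        background = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        pvals = []
        for k in range(0, 11):
            term = {f"g{i}" for i in range(k)} | {f"h{i}" for i in range(20 - k)}
            background_k = background | term
            out = hm.enrich(query, {"T": term}, background_k)
            pvals.append(out.iloc[0]["p"])
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(pvals, pvals[1:]))

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="query"):
            hm.enrich({"x"}, {"T": {"a"}}, {"a", "b"})


class TestKappaCluster:
    def test_identical_terms_merge(self):
        members = {"t1": {"a", "b", "c"}, "t2": {"a", "b", "c"}}
        clusters = hm.kappa_cluster(members, {"t1": 0.01, "t2": 0.02})
        assert len(clusters) == 1
        assert clusters[0]["representative"] == "t1"

    def test_disjoint_terms_split(self):
        members = {"t1": {"a", "b"}, "t2": {"c", "d"}}
        clusters = hm.kappa_cluster(members, {"t1": 0.01, "t2": 0.02})
        assert len(clusters) == 2

    def test_planted_blocks_recovered(self):
        # 10 terms in two blocks with high within-block membership overlap
        core1, core2 = {f"a{i}" for i in range(12)}, {f"b{i}" for i in range(12)}
        members, pvals = {}, {}
        for j in range(5):
            members[f"x{j}"] = core1 - {f"a{j}"}
            members[f"y{j}"] = core2 - {f"b{j}"}
            pvals[f"x{j}"] = 0.001 * (j + 1)
            pvals[f"y{j}"] = 0.002 * (j + 1)
        clusters = hm.kappa_cluster(members, pvals, threshold=0.3)
        blocks = {frozenset(c["members"]) for c in clusters}
        assert len(clusters) == 2
        assert blocks == {frozenset(f"x{j}" for j in range(5)),
                          frozenset(f"y{j}" for j in range(5))}

    def test_kappa_bounds(self, rng):
        for _ in range(20):
            a, b = rng.random(30) < 0.5, rng.random(30) < 0.5
            k = hm.cohen_kappa(a, b)
            assert -1.0 - 1e-9 <= k <= 1.0 + 1e-9
        assert hm.cohen_kappa(np.ones(5, bool), np.ones(5, bool)) == 1.0


class TestGeneListAnnotate:
    def make_hallmark(self, regions):
        return HallmarkSet(name="PP", region_ids=set(regions),
                           provenance={r: "preR-unique" for r in regions},
                           log2fc={r: 1.0 for r in regions})

    def test_pathway_flag_boundary_at_three_dmrs(self):
        # region ids map to genes; pathway hit by 2 DMRs is not flagged, 3 is
        h2 = self.make_hallmark(["r1", "r2"])
        h3 = self.make_hallmark(["r1", "r2", "r3"])
        mapping = {"r1": "G1", "r2": "G2", "r3": "G3"}
        lists = {"CHP": {"G1", "G2", "G3"}}
        assert not hm.gene_list_annotate(h2, mapping, lists).iloc[0]["flagged"]
        assert hm.gene_list_annotate(h3, mapping, lists).iloc[0]["flagged"]

    def test_empty_list_empty_overlap(self):
        h = self.make_hallmark(["r1"])
        out = hm.gene_list_annotate(h, {"r1": "G1"}, {"empty": set()})
        assert out.iloc[0]["overlap_genes"] == []

    def test_superset_hallmark_covers_list(self):
        h = self.make_hallmark(["r1", "r2", "r3"])
        mapping = {"r1": "G1", "r2": "G2", "r3": "G3"}
        out = hm.gene_list_annotate(h, mapping, {"L": {"G1", "G2"}})
        assert out.iloc[0]["overlap_genes"] == ["G1", "G2"]


def _bruteforce_average_linkage(dist: np.ndarray):
    """Merge-order oracle: naive average linkage over the distance matrix."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    merges = []
    while len(clusters) > 1:
        best, pair = np.inf, None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            if d < best - 1e-12:
                best, pair = d, (i, j)
        i, j = pair
        merges.append((sorted(clusters[i] + clusters[j]), best))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return merges


class TestClusterSamples:
    def test_identical_samples_distance_zero(self):
        df = pd.DataFrame({"s1": [1, 2, 3, 4], "s2": [1, 2, 3, 4],
                           "s3": [4, 3, 2, 1]})
        Z, order = hm.cluster_samples(df)
        # first merge joins the identical pair at height 0
        assert Z[0, 2] == pytest.approx(0.0)
        assert {order.index("s1"), order.index("s2")} in (
            {0, 1}, {1, 2},
        )

    def test_anticorrelated_distance_two(self):
        df = pd.DataFrame({"s1": [1, 2, 3], "s2": [3, 2, 1]})
        rho = df.corr(method="spearman").iloc[0, 1]
        assert 1 - rho == pytest.approx(2.0)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"s1": [1, 1, 1], "s2": [1, 2, 3]})
        with pytest.raises(ValueError, match="constant"):
            hm.cluster_samples(df)

    def test_merge_heights_match_bruteforce_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 5)),
                          columns=[f"s{i}" for i in range(5)])
        Z, _ = hm.cluster_samples(df)
        dist = 1 - df.corr(method="spearman").to_numpy()
        np.fill_diagonal(dist, 0)
        merges = _bruteforce_average_linkage(dist)
        assert np.allclose(sorted(Z[:, 2]), sorted(h for _, h in merges),
                           atol=1e-9)
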