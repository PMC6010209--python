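import itertools

import numpy as np
import pytest

from conftest import make_dataset
from dropkit.umi_correction import (
    AdjacencyPrior,
    GeneUmiGroup,
    NeighborhoodView,
    QualityModel,
    adjacent_umis,
    bayesian_filter,
    cluster_filter,
    collisions_among_errors,
    directional_filter,
    error_count_distribution,
    filter_dataset,
    hamming,
    partition_probability,
    posterior_error_count,
    real_count_distribution,
    search_order,
    train_quality_model,
)
from dropkit.umi_distribution import estimate_umi_distribution


def group_of(umis_reads, cell="CCCC", gene="g1", qual=35.0):
    return GeneUmiGroup(
        cell,
        gene,
        {u: (r, np.full(len(u), qual)) for u, r in umis_reads.items()},
    )


class TestAdjacency:
    def test_isolated_umi(self):
        view = adjacent_umis("AAAA", group_of({"AAAA": 10}))
        assert view.n_s == 0 and view.n_l == 0

    def test_split_small_large(self):
        g = group_of({"AAAA": 10, "AAAT": 3, "TAAA": 12})
        view = adjacent_umis("AAAA", g)
        assert view.small == ["AAAT"] and view.large == ["TAAA"]

    def test_read_tie_counts_as_small(self):
        g = group_of({"AAAA": 10, "AAAT": 10})
        assert adjacent_umis("AAAA", g).n_s == 1

    def test_absent_umi_raises(self):
        with pytest.raises(KeyError):
            adjacent_umis("TTTT", group_of({"AAAA": 1}))

    def test_matches_pairwise_hamming_oracle(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            umis = {
                "".join(rng.choice(bases, 4)): int(rng.integers(1, 20))
                for _ in range(rng.integers(2, 12))
            }
            g = group_of(umis)
            for u in umis:
                view = adjacent_umis(u, g)
                oracle = [v for v in umis if v != u and hamming(u, v) == 1]
                assert sorted(view.small + view.large) == sorted(oracle)
                assert view.n_s == sum(1 for v in oracle if umis[v] <= umis[u])


class TestClusterFilter:
    def test_drops_smaller_adjacent(self):
        assert cluster_filter(group_of({"AAAA": 10, "AAAT": 1})) == {"AAAA"}

    def test_distant_umis_kept(self):
        assert cluster_filter(group_of({"AAAA": 5, "TTTT": 5})) == {"AAAA", "TTTT"}

    def test_equal_sizes_tie_break(self):
        g = group_of({"AAAA": 5, "AAAT": 5})
        assert cluster_filter(g) == {"AAAA"}  # lexicographically smaller survives
        assert cluster_filter(g, neq=True) == {"AAAA", "AAAT"}


class TestDirectionalFilter:
    def test_more_than_twice_dropped(self):
        assert directional_filter(group_of({"AAAA": 10, "AAAT": 4})) == {"AAAA"}

    def test_exactly_twice_kept(self):
        assert directional_filter(group_of({"AAAA": 10, "AAAT": 5})) == {"AAAA", "AAAT"}

    def test_chain_matches_network_oracle(self):
        # A-B-C chain: every UMI with any incoming heavy edge is removed
        g = group_of({"AAAA": 100, "AAAT": 40, "AATT": 15})
        kept = directional_filter(g)
        oracle = {
            u
            for u in g.umis
            if not any(
                hamming(u, v) == 1 and g.reads(v) > 2 * g.reads(u) for v in g.umis
            )
        }
        assert kept == oracle == {"AAAA"}


class TestQualityModel:
    def test_p_e_printed_formula(self):
        rows = [
            ("CCCC", "AAAA", "g1", 9, 35.0),
            ("CCCC", "AAAT", "g1", 1, 12.0),
            ("CCCC", "GGGG", "g2", 8, 35.0),
            ("CCCC", "GGGT", "g2", 2, 12.0),
        ]
        qm = train_quality_model(make_dataset(rows))
        assert qm.p_e == pytest.approx(3 / 20)

    def test_k1_degenerate_quantization(self):
        rows = [
            ("CCCC", "AAAA", "g1", 9, 35.0),
            ("CCCC", "AAAT", "g1", 1, 12.0),
        ]
        qm = train_quality_model(make_dataset(rows), k_q=1)
        assert len(qm.support) == 1
        assert qm.p_q[0] == 1.0 and qm.p_q_err[0] == 1.0
        assert qm.likelihood_ratio([35.0])[0] == pytest.approx(1.0)

    def test_no_training_pairs_raises(self):
        with pytest.raises(ValueError, match="cluster"):
            train_quality_model(make_dataset([("CCCC", "AAAA", "g1", 5)]))

    def test_error_quality_separation_on_synthetic(self, saturated, saturated_dist):
        data, _ = saturated
        qm = train_quality_model(data, dist=saturated_dist)
        # injected errors carry ~Q12; the lowest support point should hold
        # far more conditional-error mass than marginal mass
        low = int(np.argmin(qm.support))
        assert qm.p_q_err[low] > 3 * qm.p_q[low]
        # corrected per-read rate is near the generative 1% rate, far from
        # the raw conditional ratio
        assert qm.p_e < 0.05


class TestAdjacencyPrior:
    def test_single_pick_column(self):
        prior = AdjacencyPrior(2)
        np.testing.assert_allclose(prior.table(0.3, 1)[:2], [0.7, 0.3])

    def test_zero_adjacent_row_is_geometric(self):
        prior = AdjacencyPrior(2)
        for s in (1, 3, 7):
            assert prior.table(0.3, s)[0] == pytest.approx(0.7**s)

    def test_columns_are_distributions(self):
        prior = AdjacencyPrior(3)
        for p in (0.05, 0.5, 1.0):
            for s in (1, 5, 20):
                assert prior.table(p, s).sum() == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_agreement(self):
        prior = AdjacencyPrior(2)  # K = 6
        rng = np.random.default_rng(1)
        K, p, picks, reps = 6, 0.3, 7, 30_000
        counts = np.zeros(K + 1)
        for _ in range(reps):
            seen = set()
            for _ in range(picks):
                if rng.random() < p:
                    seen.add(int(rng.integers(K)))
            counts[len(seen)] += 1
        tv = 0.5 * np.abs(counts / reps - prior.table(p, picks)).sum()
        assert tv < 0.02

    def test_tail_monotone_in_p_adjacent(self):
        prior = AdjacencyPrior(2)
        t1, t2 = prior.tail(0.1, 6), prior.tail(0.4, 6)
        assert np.all(t2 >= t1 - 1e-12)


class TestRealCountDistribution:
    def test_empty_support_point_mass(self):
        prior = AdjacencyPrior(2)
        np.testing.assert_allclose(real_count_distribution(0, 1, 5, 0.2, prior), [1.0])

    def test_small_p_adj_concentrates_at_zero(self):
        prior = AdjacencyPrior(2)
        pmf = real_count_distribution(3, 0, 5, 1e-9, prior)
        assert pmf[0] > 0.95

    def test_exhaustive_enumeration_oracle(self):
        """Conditioned picking-process enumeration (K=6, S_g=5, N_L=1, N_S=2)."""
        K, s_g, n_l, n_s, p = 6, 5, 1, 2, 0.2
        prior = AdjacencyPrior(2)
        picks = s_g - 1
        # enumerate all outcomes: each pick is (no-adjacent) or one of K slots
        pmf_n = np.zeros(K + 1)
        for outcome in itertools.product(range(K + 1), repeat=picks):
            prob = 1.0
            for o in outcome:
                prob *= (1 - p) if o == K else p / K
            pmf_n[len({o for o in outcome if o < K})] += prob
        # condition on N' >= N_L, support 0..N_S: P(#Real = n) ∝ P(N' = n + N_L)
        w = np.array([pmf_n[n + n_l] for n in range(n_s + 1)])
        expected = w / w.sum()
        np.testing.assert_allclose(
            real_count_distribution(n_s, n_l, s_g, p, prior), expected, atol=1e-12
        )


class TestErrorCountDistribution:
    def test_single_candidate_weight(self):
        from scipy.stats import binom

        d = error_count_distribution(np.array([1]), 9, 0.1)
        w0, w1 = binom.pmf(0, 9, 0.1), binom.pmf(1, 10, 0.1)
        np.testing.assert_allclose(d, [w0 / (w0 + w1), w1 / (w0 + w1)])

    def test_small_p_e_degenerates_to_zero_errors(self):
        d = error_count_distribution(np.array([2, 3]), 10, 1e-9)
        assert d[0] > 0.999

    def test_three_candidates_hand_computed(self):
        from scipy.stats import binom

        reads = np.array([1, 1, 2])
        R, pe = 10, 0.2
        r_cum = [0, 1, 2, 4]
        w = np.array([binom.pmf(rc, R + rc, pe) for rc in r_cum])
        np.testing.assert_allclose(error_count_distribution(reads, R, pe), w / w.sum())

    def test_invalid_rate_raises(self):
        with pytest.raises(ValueError):
            error_count_distribution(np.array([1]), 5, 1.5)


class TestCollisionsAmongErrors:
    def test_single_event_cannot_collide(self):
        assert collisions_among_errors(1, 1, AdjacencyPrior(2)) == pytest.approx(1.0)

    def test_two_events_k6(self):
        prior = AdjacencyPrior(2)
        assert collisions_among_errors(2, 2, prior) == pytest.approx(5 / 6)
        assert collisions_among_errors(1, 2, prior) == pytest.approx(1 / 6)

    def test_occupancy_brute_force_k12(self):
        prior = AdjacencyPrior(4)  # K = 12
        total = 4
        counts = np.zeros(13)
        for t in itertools.product(range(12), repeat=total):
            counts[len(set(t))] += 1
        counts /= 12**total
        for observed in range(1, total + 1):
            assert collisions_among_errors(observed, total, prior) == pytest.approx(
                counts[observed], abs=1e-12
            )


def toy_quality_model():
    support = np.array([12.0, 25.0, 35.0])
    return QualityModel(support, np.array([0.2, 0.3, 0.5]), np.array([0.7, 0.2, 0.1]), 0.05)


class TestPosterior:
    def test_empty_neighborhood(self):
        qm = toy_quality_model()
        view = NeighborhoodView("AAAA", 10, [], [], np.array([], dtype=int), np.array([]))
        post = posterior_error_count(view, qm, AdjacencyPrior(1), 0.1)
        assert post.map_count == 0 and post.probs[0] == 1.0

    def test_large_neighbors_never_candidates(self):
        g = group_of({"AAAA": 5, "TAAA": 50})
        view = adjacent_umis("AAAA", g)
        assert view.n_s == 0 and view.n_l == 1
        post = posterior_error_count(view, toy_quality_model(), AdjacencyPrior(1), 0.1)
        assert post.map_count == 0

    def test_nested_posterior_equals_exhaustive_restriction(self):
        """Nested-split posterior == exhaustive enumeration restricted to the
        nested splits, for random neighborhoods."""
        rng = np.random.default_rng(2)
        qm = toy_quality_model()
        prior = AdjacencyPrior(2)
        for _ in range(30):
            n_s = int(rng.integers(1, 6))
            view = NeighborhoodView(
                "AAAAAA",
                int(rng.integers(5, 40)),
                [f"u{i}" for i in range(n_s)],
                [],
                rng.integers(1, 5, n_s),
                rng.choice(qm.support, n_s),
            )
            p_adj = float(rng.uniform(0.01, 0.4))
            post = posterior_error_count(view, qm, prior, p_adj)
            order = search_order(view, qm)
            weights = np.array(
                [
                    partition_probability(view, order[:j], qm, prior, p_adj)
                    for j in range(n_s + 1)
                ]
            )
            np.testing.assert_allclose(post.probs, weights / weights.sum(), atol=1e-12)

    def test_all_splits_normalize(self):
        """Probabilities over every split of a 4-candidate neighborhood sum
        to 1 after normalization (sanity of the unnormalized weights)."""
        qm = toy_quality_model()
        prior = AdjacencyPrior(2)
        view = NeighborhoodView(
            "AAAAAA", 20, ["a", "b", "c", "d"], [], np.array([1, 2, 3, 4]),
            np.array([12.0, 25.0, 35.0, 35.0]),
        )
        weights = [
            partition_probability(view, np.array(c, dtype=int), qm, prior, 0.1)
            for r in range(5)
            for c in itertools.combinations(range(4), r)
        ]
        total = sum(weights)
        assert total > 0
        np.testing.assert_allclose(sum(w / total for w in weights), 1.0, atol=1e-12)


class TestBayesianFilter:
    def test_identity_without_adjacent_pairs(self):
        rows = [
            ("CCCC", "AAAA", "g1", 9, 35.0),
            ("CCCC", "AAAT", "g1", 1, 12.0),  # training pair in another gene
            ("CCCC", "GGGG", "g2", 5, 35.0),
            ("CCCC", "CCTT", "g2", 5, 35.0),
        ]
        data = make_dataset(rows)
        dist = estimate_umi_distribution(data)
        qm = train_quality_model(data)
        out, _ = bayesian_filter(data, dist, qm)
        g2 = out.df[out.df["gene"] == "g2"]
        assert set(g2["umi"]) == {"GGGG", "CCTT"}

    def test_injected_error_removed_and_reads_reassigned(self):
        rows = [
            ("CCCC", "AAAA", "g1", 50, 35.0),
            ("CCCC", "AAAT", "g1", 1, 10.0),
            # extra two-UMI training genes
            ("CCCC", "GGGG", "g2", 30, 35.0),
            ("CCCC", "GGGT", "g2", 1, 10.0),
            ("CCCC", "TTTT", "g3", 20, 35.0),
            ("CCCC", "TTTA", "g3", 1, 10.0),
        ]
        data = make_dataset(rows)
        dist = estimate_umi_distribution(data)
        qm = train_quality_model(data)
        out, audit = bayesian_filter(data, dist, qm, collect_audit=True)
        g1 = out.df[out.df["gene"] == "g1"]
        assert list(g1["umi"]) == ["AAAA"]
        assert g1["reads"].iloc[0] == 51
        assert (audit["method"] == "bayesian").all()

    def test_read_conservation_on_synthetic(self, saturated, saturated_dist):
        data, _ = saturated
        for method in ("cluster", "cluster-neq", "directional"):
            out = filter_dataset(data, method)
            assert out.total_reads == data.total_reads

    def test_group_sizes_never_increase(self, saturated, saturated_dist):
        data, _ = saturated
        sub_idx = np.flatnonzero(
            data.df["cb"].isin(data.df["cb"].unique()[:3]).to_numpy()
        )
        sub = data.subset(sub_idx)
        qm = train_quality_model(data, dist=saturated_dist)
        out, _ = bayesian_filter(sub, saturated_dist, qm)
        before = sub.df.groupby(["cb", "gene"]).size()
        after = out.df.groupby(["cb", "gene"]).size()
        joined = before.to_frame("b").join(after.to_frame("a")).fillna(0)
        assert (joined["a"] <= joined["b"]).all()
        assert out.total_reads == sub.total_reads
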