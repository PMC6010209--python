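import itertools

import numpy as np
import pytest

from conftest import make_dataset
from dropkit.cb_correction import (
    CellComposition,
    MergePlan,
    apply_merge,
    build_compositions,
    cross_species_merge_audit,
    expected_intersection,
    merge_known_barcodes,
    merge_poisson,
    merge_simple,
    observed_intersection,
    poisson_merge_test,
)
from dropkit.simulate import SimulationConfig, merge_metrics, simulate_dataset
from dropkit.umi_distribution import UmiDistribution, estimate_umi_distribution


def comp(cb, genes):
    return CellComposition(cb, {g: frozenset(u) for g, u in genes.items()})


class TestObservedIntersection:
    def test_disjoint_genes(self):
        a = comp("AAAA", {"g1": {"AA"}})
        b = comp("AAAT", {"g2": {"AA"}})
        assert observed_intersection(a, b) == 0

    def test_identical(self):
        a = comp("AAAA", {"g1": {"AA", "AC"}, "g2": {"TT"}})
        assert observed_intersection(a, a) == 3

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        umis = ["AA", "AC", "AG", "AT", "CA", "CC"]
        for _ in range(50):
            a = comp("AAAA", {f"g{i}": set(rng.choice(umis, rng.integers(1, 4), replace=False)) for i in range(4)})
            b = comp("AAAT", {f"g{i}": set(rng.choice(umis, rng.integers(1, 4), replace=False)) for i in rng.choice(6, 3, replace=False)})
            oracle = sum(
                len(a.genes[g] & b.genes[g]) for g in set(a.genes) & set(b.genes)
            )
            assert observed_intersection(a, b) == oracle


class TestExpectedIntersection:
    def test_no_shared_genes(self):
        dist = UmiDistribution(["AA", "AC"], np.array([0.5, 0.5]), 2)
        a = comp("AAAA", {"g1": {"AA"}})
        b = comp("AAAT", {"g2": {"AA"}})
        assert expected_intersection(a, b, dist) == 0.0

    def test_uniform_single_molecule_closed_form(self):
        seqs = ["".join(t) for t in itertools.product("ACGT", repeat=2)]
        dist = UmiDistribution(seqs, np.full(16, 1 / 16), 2)
        a = comp("AAAA", {"g1": {"AA"}})
        b = comp("AAAT", {"g1": {"CC"}})
        assert expected_intersection(a, b, dist) == pytest.approx(1 / 16)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(t) for t in itertools.product("ACGT", repeat=2)]
        dist = UmiDistribution(seqs, rng.dirichlet(np.full(16, 1.0)), 2)
        a = comp("AAAA", {"g1": {"AA", "AC", "CA"}, "g2": {"TT"}})
        b = comp("AAAT", {"g1": {"AA", "GG"}, "g2": {"TT", "TA"}})
        assert expected_intersection(a, b, dist) == pytest.approx(
            expected_intersection(b, a, dist)
        )

    def test_monte_carlo_oracle(self):
        """Gene sizes (5, 8) under a skewed 16-UMI pool: EC matches sampling."""
        rng = np.random.default_rng(7)
        seqs = ["".join(t) for t in itertools.product("ACGT", repeat=2)]
        probs = rng.dirichlet(np.full(16, 2.0))
        dist = UmiDistribution(seqs, probs, 2)
        a = comp("AAAA", {"g1": set(seqs[:5])})
        b = comp("AAAT", {"g1": set(seqs[5:13])})
        # draw both compositions independently: 5 and 8 molecules, distinct
        # UMIs kept, intersect
        reps = 30_000
        sizes = np.zeros(reps)
        for i in range(reps):
            sa = set(rng.choice(16, 5, p=probs))
            sb = set(rng.choice(16, 8, p=probs))
            sizes[i] = len(sa & sb)
        mc = sizes.mean()
        se = sizes.std(ddof=1) / np.sqrt(reps)
        # EC uses collision-adjusted draws: molecule counts 5 and 8 give the
        # same expected overlap as the Monte-Carlo distinct sets
        ec = expected_intersection(a, b, dist)
        assert abs(ec - mc) < max(3 * se, 0.02)


class TestPoissonTest:
    def test_zero_intersection(self):
        assert poisson_merge_test(0, 5.0) == 1.0

    def test_closed_form(self):
        expected = 1 - np.exp(-0.5) * (1 + 0.5 + 0.125)
        assert poisson_merge_test(3, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_series_oracle(self):
        rng = np.random.default_rng(3)
        from math import exp, factorial

        for _ in range(100):
            C = int(rng.integers(1, 12))
            EC = float(rng.uniform(0.01, 8.0))
            series = 1.0 - sum(exp(-EC) * EC**i / factorial(i) for i in range(C))
            assert poisson_merge_test(C, EC) == pytest.approx(series, abs=1e-10)


@pytest.fixture(scope="module")
def merged_setup():
    cfg = SimulationConfig(seed=2)
    data, truth = simulate_dataset(cfg)
    dist = estimate_umi_distribution(data)
    comps = build_compositions(data)
    return data, truth, dist, comps


class TestMergePoisson:
    def test_distant_cbs_never_candidates(self):
        dist = UmiDistribution(["AA", "AC"], np.array([0.5, 0.5]), 2)
        cells = {
            "AAAAAA": comp("AAAAAA", {"g1": {"AA"}}),
            "TTTAAA": comp("TTTAAA", {"g1": {"AA"}}),  # Hamming 3
        }
        plan = merge_poisson(cells, dist, max_hamming=2, alpha=0.5)
        assert len(plan) == 0

    def test_disjoint_compositions_not_merged(self):
        seqs = ["".join(t) for t in itertools.product("ACGT", repeat=2)]
        dist = UmiDistribution(seqs, np.full(16, 1 / 16), 2)
        cells = {
            "AAAA": comp("AAAA", {"g1": {"AA", "AC"}, "g2": {"GG"}}),
            "AAAT": comp("AAAT", {"g3": {"TT"}}),
        }
        plan = merge_poisson(cells, dist, alpha=0.05)
        assert len(plan) == 0

    def test_split_children_recovered(self, merged_setup):
        data, truth, dist, comps = merged_setup
        plan = merge_poisson(comps, dist)
        m = merge_metrics(plan.targets, truth)
        assert m["recovery_rate"] >= 0.95
        assert m["false_merges"] <= 1

    def test_plan_is_forest(self, merged_setup):
        data, truth, dist, comps = merged_setup
        plan = merge_poisson(comps, dist)
        targets = set(t for t in plan.targets.values() if t is not None)
        assert not targets & set(plan.targets)


class TestMergeSimple:
    def test_isolated_kept(self):
        cells = {"AAAA": comp("AAAA", {"g1": {"AA"}}), "TTTT": comp("TTTT", {"g1": {"AC"}})}
        assert len(merge_simple(cells)) == 0

    def test_merges_into_largest_neighbor(self):
        cells = {
            "AAAA": comp("AAAA", {"g1": {"AA"}}),
            "AAAT": comp("AAAT", {"g1": {"AA", "AC"}}),
            "AATA": comp("AATA", {"g1": {"AA", "AC", "AG"}}),
        }
        plan = merge_simple(cells)
        assert plan.targets["AAAA"] == "AATA"

    def test_simple_merges_more_than_poisson(self, merged_setup):
        data, truth, dist, comps = merged_setup
        assert len(merge_simple(comps)) > len(merge_poisson(comps, dist))


class TestMergeKnown:
    def test_whitelisted_unchanged(self):
        cells = {"AAAA": comp("AAAA", {"g1": {"AA"}})}
        plan = merge_known_barcodes(cells, ["AAAA"])
        assert len(plan) == 0

    def test_single_neighbor_reassigned(self):
        cells = {
            "AAAT": comp("AAAT", {"g1": {"AA"}}),
            "AAAA": comp("AAAA", {"g1": {"AA", "AC"}}),
        }
        plan = merge_known_barcodes(cells, ["AAAA"])
        assert plan.targets["AAAT"] == "AAAA"

    def test_far_cb_dropped(self):
        cells = {
            "TTTT": comp("TTTT", {"g1": {"AA"}}),
            "AAAA": comp("AAAA", {"g1": {"AA", "AC"}}),
        }
        plan = merge_known_barcodes(cells, ["AAAA"], max_hamming=2)
        assert plan.targets["TTTT"] is None

    def test_empty_whitelist_raises(self):
        with pytest.raises(ValueError):
            merge_known_barcodes({}, [])


class TestApplyMerge:
    def test_empty_plan_identity(self):
        data = make_dataset([("AAAA", "AA", "g1", 2)])
        out = apply_merge(data, MergePlan())
        assert out.total_reads == data.total_reads and len(out) == len(data)

    def test_union_semantics_and_read_conservation(self):
        data = make_dataset(
            [
                ("AAAA", "AA", "g1", 5),
                ("AAAT", "AA", "g1", 2),  # same molecule split across CBs
                ("AAAT", "AC", "g1", 3),
            ]
        )
        plan = MergePlan({"AAAT": "AAAA"})
        out = apply_merge(data, plan)
        assert out.total_reads == 10
        merged = out.df[out.df["cb"] == "AAAA"]
        assert sorted(merged["umi"]) == ["AA", "AC"]
        assert merged.set_index("umi")["reads"]["AA"] == 7

    def test_chained_plan_rejected(self):
        data = make_dataset([("AAAA", "AA", "g1", 1)])
        with pytest.raises(ValueError):
            apply_merge(data, MergePlan({"AAAT": "AAAA", "AAAA": "AATT"}))


class TestCrossSpeciesAudit:
    def test_no_merges(self, merged_setup):
        data, truth, dist, comps = merged_setup
        report = cross_species_merge_audit(MergePlan(), data, {}, min_genes=1, n_real=10)
        assert report["n_merges"] == 0 and report["mixed_fraction"] == 0.0

    def test_poisson_cleaner_than_simple(self):
        # more cells -> more injected splits, so the merge fractions are
        # stable enough to compare
        cfg = SimulationConfig(
            seed=6, two_species=True, n_cells=60, n_background=600, umi_error_rate=0.0
        )
        data, truth = simulate_dataset(cfg)
        dist = estimate_umi_distribution(data)
        comps = build_compositions(data)
        species = {
            g: ("human" if g.startswith("hs_") else "mouse")
            for g in data.df["gene"].unique()
            if g != "__intergenic__"
        }
        audit_p = cross_species_merge_audit(
            merge_poisson(comps, dist), data, species, min_genes=5, n_real=cfg.n_cells
        )
        audit_s = cross_species_merge_audit(
            merge_simple(comps), data, species, min_genes=5, n_real=cfg.n_cells
        )
        assert audit_p["mixed_fraction"] < 0.1
        assert audit_s["mixed_fraction"] >= 5 * audit_p["mixed_fraction"]
        assert audit_s["mixed_fraction"] > 0.05

    def test_poisson_agrees_with_known_barcodes(self, merged_setup):
        data, truth, dist, comps = merged_setup
        whitelist = sorted(truth.cells.index)
        plan_known = merge_known_barcodes(comps, whitelist, dist)
        plan_poisson = merge_poisson(comps, dist)
        report = cross_species_merge_audit(
            plan_poisson,
            data,
            {},
            min_genes=1,
            n_real=len(truth.cells),
            reference_plan=plan_known,
        )
        if report["agreement_with_reference"] is not None:
            assert report["agreement_with_reference"] >= 0.9
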