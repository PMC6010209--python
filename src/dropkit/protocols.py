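"""End-to-end validation protocols.

Each function runs one self-contained benchmark of the package against an
independent oracle (closed form, exhaustive enumeration, Monte-Carlo
simulation, or generator ground truth) and returns plain numbers.  The
test suite asserts on them; the acceptance script reports them.
"""

from __future__ import annotations

import itertools

import numpy as np

from dropkit import cb_correction, diagnostics, simulate, umi_correction
from dropkit.simulate import SimulationConfig, simulate_dataset
from dropkit.umi_distribution import (
    UmiDistribution,
    build_collision_table,
    estimate_umi_distribution,
)

__all__ = [
    "collision_closed_form_error",
    "collision_bootstrap_check",
    "adjacency_prior_tv",
    "collision_occupancy_max_error",
    "posterior_exhaustive_max_error",
    "umi_method_comparison",
    "collision_adjustment_comparison",
    "cb_merge_benchmark",
    "two_species_audit",
]


def collision_closed_form_error(pool_exponents=(3, 4, 6)) -> dict[int, float]:
    """Max relative error of the stepwise empirical table vs the uniform
    closed form, per pool size m = 4^L, over k <= 0.9 m."""
    out = {}
    for L in pool_exponents:
        m = 4**L
        table = build_collision_table(UmiDistribution.uniform_pool(L))
        ks = np.arange(1, int(0.9 * m) + 1)
        closed = -m * np.log1p(-ks / m)
        out[m] = float(
            np.max(np.abs(table.n_of_k[ks - 1] - closed) / np.maximum(closed, 1e-12))
        )
    return out


def collision_bootstrap_check(seed: int = 0, ks=(10, 50, 100), reps: int = 1000) -> dict:
    """Stepwise table vs bootstrap oracle on a skewed 256-UMI pool.

    The oracle samples UMIs one at a time until k distinct are seen and
    averages the number of draws; the check is whether n(k) falls in the
    99% CI of that mean."""
    rng = np.random.default_rng(seed)
    seqs = ["".join(t) for t in itertools.product("ACGT", repeat=4)]
    probs = rng.dirichlet(np.full(256, 1.0))
    dist = UmiDistribution(seqs, probs, 4)
    table = build_collision_table(dist)
    out = {}
    for k in ks:
        draws = np.empty(reps)
        for r in range(reps):
            batch = rng.choice(256, size=1024, p=probs)
            _, first = np.unique(batch, return_index=True)
            first = np.sort(first)
            draws[r] = first[k - 1] + 1
        mean = draws.mean()
        half = 2.576 * draws.std(ddof=1) / np.sqrt(reps)
        out[k] = {
            "n_k": float(table.lookup(k)),
            "ci_lo": float(mean - half),
            "ci_hi": float(mean + half),
            "inside": bool(mean - half <= table.lookup(k) <= mean + half),
        }
    return out


def adjacency_prior_tv(seed: int = 0, reps: int = 100_000) -> float:
    """Max total-variation distance between the DP occupancy prior (K = 6)
    and direct Monte-Carlo simulation, over gene sizes up to 8."""
    prior = umi_correction.AdjacencyPrior(2)  # K = 6
    rng = np.random.default_rng(seed)
    K, p = 6, 0.3
    worst = 0.0
    for s_g in (2, 5, 8):
        picks = s_g - 1
        hits = rng.random((reps, picks)) < p
        slots = rng.integers(0, K, size=(reps, picks))
        counts = np.zeros(K + 1)
        for r in range(reps):
            counts[len(set(slots[r][hits[r]]))] += 1
        tv = 0.5 * np.abs(counts / reps - prior.table(p, picks)).sum()
        worst = max(worst, float(tv))
    return worst


def collision_occupancy_max_error(total: int = 4, K: int = 12) -> float:
    """Exact enumeration of the error-collision occupancy problem vs the
    p_adjacent = 1 DP table."""
    prior = umi_correction.AdjacencyPrior(K // 3)
    counts = np.zeros(K + 1)
    for t in itertools.product(range(K), repeat=total):
        counts[len(set(t))] += 1
    counts /= K**total
    return float(
        max(
            abs(umi_correction.collisions_among_errors(d, total, prior) - counts[d])
            for d in range(1, total + 1)
        )
    )


def posterior_exhaustive_max_error(seed: int = 0, n_neighborhoods: int = 200) -> float:
    """Nested-order posterior vs exhaustive 2^|neighborhood| enumeration
    restricted to the nested splits, on random neighborhoods (|Ω| <= 10)."""
    rng = np.random.default_rng(seed)
    prior = umi_correction.AdjacencyPrior(6)  # K = 18, 6-base UMIs
    support = np.array([8.0, 15.0, 25.0, 33.0, 37.0])
    qm = umi_correction.QualityModel(
        support,
        np.array([0.15, 0.15, 0.2, 0.3, 0.2]),
        np.array([0.5, 0.25, 0.15, 0.07, 0.03]),
        0.02,
    )
    worst = 0.0
    for _ in range(n_neighborhoods):
        n_s = int(rng.integers(1, 11))
        n_l = int(rng.integers(0, 3))
        R = int(rng.integers(3, 60))
        view = umi_correction.NeighborhoodView(
            "AAAAAA",
            R,
            [f"u{i}" for i in range(n_s)],
            [f"L{i}" for i in range(n_l)],
            np.minimum(rng.integers(1, 8, n_s), R),
            rng.choice(support, n_s),
        )
        p_adj = float(rng.uniform(0.005, 0.3))
        post = umi_correction.posterior_error_count(view, qm, prior, p_adj)
        order = umi_correction.search_order(view, qm)
        nested = {tuple(sorted(order[:j])): j for j in range(n_s + 1)}
        weights = np.zeros(n_s + 1)
        for r in range(n_s + 1):
            for comb in itertools.combinations(range(n_s), r):
                j = nested.get(tuple(sorted(comb)))
                if j is not None:
                    weights[j] = umi_correction.partition_probability(
                        view, np.array(comb, dtype=int), qm, prior, p_adj
                    )
        weights /= weights.sum()
        worst = max(worst, float(np.max(np.abs(weights - post.probs))))
    return worst


def umi_method_comparison(seed: int = 1) -> dict:
    """F1 of erroneous-molecule removal and post-correction edit-distance
    misfit for every correction method on the default saturated library."""
    data, truth = simulate_dataset(SimulationConfig(seed=seed))
    dist = estimate_umi_distribution(data)
    qm = umi_correction.train_quality_model(data, dist=dist)
    prior = umi_correction.AdjacencyPrior(data.umi_length)
    out = {}
    for method in ("cluster", "cluster-neq", "directional"):
        corrected = umi_correction.filter_dataset(data, method)
        m = simulate.umi_correction_metrics(data, corrected, truth)
        profile = diagnostics.edit_distance_profile(corrected, dist, seed=seed)
        out[method] = {"f1": m["f1"], "edit_misfit": profile.total_relative_difference}
    corrected, _ = umi_correction.bayesian_filter(data, dist, qm, prior)
    m = simulate.umi_correction_metrics(data, corrected, truth)
    profile = diagnostics.edit_distance_profile(corrected, dist, seed=seed)
    out["bayesian"] = {"f1": m["f1"], "edit_misfit": profile.total_relative_difference}
    return out


def collision_adjustment_comparison(seed: int = 1, trim_to: int = 4) -> dict:
    """Median |percentage count error| in the top expression decile for the
    three collision-adjustment modes after trimming the saturated library.

    The full-length benchmark and the trimmed data are both error-corrected
    with the Bayesian filter, which is near-exact at the full length."""
    data, _ = simulate_dataset(SimulationConfig(seed=seed))
    table = diagnostics.trimming_benchmark(
        data,
        [trim_to],
        methods=("bayesian",),
        adjustments=("none", "uniform", "empirical"),
        benchmark_method="bayesian",
    )
    top = table[table["decile"] == 10]
    return {
        adj: float(top.loc[top["adjustment"] == adj, "pct_error"].abs().median())
        for adj in ("none", "uniform", "empirical")
    }


def cb_merge_benchmark(seed: int = 3, alpha: float = 0.01) -> dict:
    """Null calibration and split recovery of the Poisson merge test."""
    # null: no injected CB errors, so every attempted merge is a false one
    null_cfg = SimulationConfig(seed=seed, cb_error_cell_fraction=0.0)
    data, _ = simulate_dataset(null_cfg)
    dist = estimate_umi_distribution(data)
    table = build_collision_table(dist)
    comps = cb_correction.build_compositions(data)
    plan = cb_correction.merge_poisson(comps, dist, table, alpha=alpha)
    tested = int(plan.stats["source"].nunique()) if len(plan.stats) else 0
    null_rate = len(plan) / tested if tested else 0.0

    # power: recover injected splits
    split_cfg = SimulationConfig(seed=seed + 1)
    data2, truth2 = simulate_dataset(split_cfg)
    dist2 = estimate_umi_distribution(data2)
    comps2 = cb_correction.build_compositions(data2)
    plan2 = cb_correction.merge_poisson(comps2, dist2, build_collision_table(dist2), alpha=alpha)
    metrics = simulate.merge_metrics(plan2.targets, truth2)
    return {
        "null_rate": float(null_rate),
        "null_tested": tested,
        "alpha": alpha,
        "recovery_rate": float(metrics["recovery_rate"]),
        "n_children": metrics["n_children"],
    }


def two_species_audit(seed: int = 6) -> dict:
    """Cross-species merge fractions for the Poisson and simple methods on
    a two-species mixture with injected CB splits."""
    cfg = SimulationConfig(
        seed=seed, two_species=True, n_cells=60, n_background=600, umi_error_rate=0.0
    )
    data, truth = simulate_dataset(cfg)
    dist = estimate_umi_distribution(data)
    comps = cb_correction.build_compositions(data)
    species = {
        g: ("human" if g.startswith("hs_") else "mouse")
        for g in data.df["gene"].unique()
        if g != "__intergenic__"
    }
    out = {}
    for name, plan in (
        ("poisson", cb_correction.merge_poisson(comps, dist)),
        ("simple", cb_correction.merge_simple(comps)),
    ):
        audit = cb_correction.cross_species_merge_audit(
            plan, data, species, min_genes=5, n_real=cfg.n_cells
        )
        out[name] = audit["mixed_fraction"]
        out[f"{name}_n_merges"] = audit["n_merges"]
    return out
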