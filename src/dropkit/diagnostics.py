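"""Validation machinery and run diagnostics.

The main quality check for UMI error correction compares the pooled
distribution of pairwise Hamming distances between UMIs of the same gene
against the theoretical distribution for independent draws from the common
UMI distribution: under-correction leaves an excess at distance 1,
over-correction a deficit.  The module also provides UMI trimming (which
naturally creates collisions and lets a long-UMI dataset serve as its own
benchmark for short-UMI behaviour), barcode rank / molecular-mass curves,
an adjacency-excess ratio, and a machine-readable run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dropkit.records import Dataset
from dropkit.umi_distribution import (
    CollisionTable,
    UmiDistribution,
    build_collision_table,
    estimate_umi_distribution,
)
from dropkit.umi_correction import filter_dataset, hamming, iter_groups, p_adjacent

__all__ = [
    "EditDistanceProfile",
    "observed_edit_distribution",
    "theoretical_edit_distribution",
    "edit_distance_relative_difference",
    "edit_distance_profile",
    "trim_umis",
    "trimming_benchmark",
    "rank_curves",
    "adjacency_excess",
    "run_report",
]


@dataclass
class EditDistanceProfile:
    observed: np.ndarray  # P(ED = k), k = 0..L
    theoretical: np.ndarray
    relative_difference: np.ndarray  # |P - P*| / P*, NaN where P* = 0

    @property
    def total_relative_difference(self) -> float:
        finite = self.relative_difference[np.isfinite(self.relative_difference)]
        return float(np.sum(finite))


def observed_edit_distribution(
    data: Dataset, max_group: int = 1000, seed: int = 0
) -> np.ndarray:
    """Pooled pairwise Hamming distances within each cell-gene group.

    Groups larger than ``max_group`` UMIs are subsampled (seeded) to bound
    the quadratic pair count.
    """
    rng = np.random.default_rng(seed)
    L = data.umi_length
    counts = np.zeros(L + 1, dtype=float)
    any_pairs = False
    for group in iter_groups(data):
        umis = sorted(group.umis)
        if len(umis) < 2:
            continue
        if len(umis) > max_group:
            umis = list(rng.choice(umis, size=max_group, replace=False))
        any_pairs = True
        arr = np.frombuffer("".join(umis).encode(), dtype="S1").reshape(len(umis), L)
        for i in range(len(umis)):
            d = (arr[i + 1 :] != arr[i]).sum(axis=1)
            counts += np.bincount(d, minlength=L + 1)
    if not any_pairs:
        raise ValueError("no gene has two or more UMIs; edit distances undefined")
    return counts / counts.sum()


def theoretical_edit_distribution(
    dist: UmiDistribution, n_pairs: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo distribution of the Hamming distance between two
    independent draws from the UMI distribution."""
    if n_pairs < 10_000:
        raise ValueError("use at least 10^4 pairs for a stable estimate")
    rng = np.random.default_rng(seed)
    L = dist.umi_length
    if dist.uniform:
        # closed form: each position differs independently with prob 3/4
        from scipy.stats import binom

        return binom.pmf(np.arange(L + 1), L, 0.75)
    seqs = np.array(dist.sequences, dtype=object)
    a = rng.choice(len(seqs), size=n_pairs, p=dist.probs)
    b = rng.choice(len(seqs), size=n_pairs, p=dist.probs)
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    d = (arr[a] != arr[b]).sum(axis=1)
    return np.bincount(d, minlength=L + 1) / n_pairs


def edit_distance_relative_difference(obs: np.ndarray, theo: np.ndarray) -> np.ndarray:
    """Per-distance |P - P*| / P*; undefined (NaN) where P* = 0."""
    if len(obs) != len(theo):
        raise ValueError("distribution supports are not aligned")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(obs - theo) / theo
    out[theo == 0] = np.nan
    return out


def edit_distance_profile(
    data: Dataset,
    dist: UmiDistribution,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> EditDistanceProfile:
    obs = observed_edit_distribution(data, seed=seed)
    theo = theoretical_edit_distribution(dist, n_pairs=n_pairs, seed=seed)
    return EditDistanceProfile(obs, theo, edit_distance_relative_difference(obs, theo))


# ---------------------------------------------------------------------------
# trimming benchmark
# ---------------------------------------------------------------------------


def trim_umis(data: Dataset, new_length: int, side: str = "back") -> Dataset:
    """Shorten every UMI (and its quality vector) to ``new_length`` bases.

    ``back`` trims from the end, ``front`` from the start.  Records whose
    trimmed keys collide are merged with reads summed and read-weighted mean
    qualities — exactly the signature of a UMI collision.
    """
    if not 1 <= new_length < data.umi_length:
        raise ValueError(
            f"new_length must lie in [1, {data.umi_length - 1}], got {new_length}"
        )
    df = data.df.copy()
    if side == "back":
        df["umi"] = [u[:new_length] for u in df["umi"]]
        quals = data.quals[:, :new_length]
    elif side == "front":
        df["umi"] = [u[-new_length:] for u in df["umi"]]
        quals = data.quals[:, -new_length:]
    else:
        raise ValueError("side must be 'back' or 'front'")
    return Dataset(df, quals.copy(), new_length)


def _counts(data: Dataset) -> pd.Series:
    df = data.df.loc[~data.df["intergenic"]]
    return df.groupby(["cb", "gene"]).size()


def _safe_adjust(counts: pd.Series, table: CollisionTable) -> pd.Series:
    # saturated observations beyond the table are held at the last entry
    return counts.map(lambda k: table.lookup(min(int(k), table.max_k)))


def trimming_benchmark(
    data: Dataset,
    lengths: list[int],
    methods: tuple[str, ...] = ("none", "cluster", "bayesian"),
    adjustments: tuple[str, ...] = ("none", "uniform", "empirical"),
    side: str = "back",
    benchmark_method: str = "cluster",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Percentage count error of trimmed-UMI estimates vs the full-length
    benchmark.

    The benchmark is the full-length dataset filtered with
    ``benchmark_method`` and counted per (cell, gene).  The benchmark
    filter should be near-exact at the full UMI length: the cluster filter
    when chance adjacency is rare there (long UMIs), the Bayesian filter
    for saturated full-length data.  For each trim length, UMI correction
    method and collision-adjustment mode, collision adjustment is applied
    per (cell, gene) entry and errors are summarized per gene (summed over
    cells), with expression deciles of the per-gene benchmark total.
    """
    benchmark = _counts(filter_dataset(data, benchmark_method))
    rows = []
    for length in lengths:
        trimmed = trim_umis(data, length, side=side)
        for method in methods:
            corrected = filter_dataset(trimmed, method)
            counts = _counts(corrected)
            emp_dist = estimate_umi_distribution(corrected)
            emp_table = build_collision_table(emp_dist)
            uni_table = build_collision_table(UmiDistribution.uniform_pool(length))
            for adj in adjustments:
                if adj == "none":
                    est = counts.astype(float)
                elif adj == "uniform":
                    est = _safe_adjust(counts, uni_table)
                elif adj == "empirical":
                    est = _safe_adjust(counts, emp_table)
                else:
                    raise ValueError(f"unknown adjustment {adj!r}")
                joined = pd.concat([est, benchmark], axis=1, keys=["est", "truth"])
                joined = joined.fillna(0.0)
                per_gene = joined.groupby(level=1).sum()
                per_gene = per_gene[per_gene["truth"] > 0]
                decile = np.ceil(
                    per_gene["truth"].rank(pct=True) * n_bins
                ).astype(int)
                err = 100.0 * (per_gene["est"] - per_gene["truth"]) / per_gene["truth"]
                for gene in per_gene.index:
                    rows.append(
                        {
                            "length": length,
                            "method": method,
                            "adjustment": adj,
                            "gene": gene,
                            "truth": per_gene.loc[gene, "truth"],
                            "decile": int(decile.loc[gene]),
                            "pct_error": float(err.loc[gene]),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank curves and adjacency excess
# ---------------------------------------------------------------------------


def rank_curves(sizes: pd.Series, n_bins: int = 30) -> dict:
    """Barcode rank curve and the binned molecular-mass curve (size times
    number of barcodes of similar size)."""
    s = np.sort(np.asarray(sizes, dtype=float))[::-1]
    ranks = np.arange(1, len(s) + 1)
    log_s = np.log10(np.maximum(s, 0.5))
    edges = np.linspace(log_s.min(), log_s.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(log_s, edges) - 1, 0, n_bins - 1)
    mass = np.zeros(n_bins)
    np.add.at(mass, which, s)
    centers = 10 ** ((edges[:-1] + edges[1:]) / 2)
    return {
        "rank": ranks,
        "size": s,
        "mass_bin_center": centers,
        "mass": mass,
    }


def adjacency_excess(data: Dataset, dist: UmiDistribution) -> float:
    """Observed / expected Hamming-1 pairs within genes.

    The null: for a gene with ``S`` distinct UMIs, each of the C(S, 2)
    pairs is an independent draw of two distinct UMIs from the common
    distribution, so P(adjacent) = (sum_u p(u) p_adjacent(u)) / (1 - sum_u
    p(u)^2).  Ratios well above 1 indicate sequence errors.
    """
    vals = dist.probs
    p0 = float(np.sum(vals**2))
    p1 = float(sum(p * p_adjacent(u, dist) for u, p in zip(dist.sequences, vals)))
    if 1.0 - p0 <= 0:
        raise ValueError("degenerate UMI distribution")
    p_adj_pair = p1 / (1.0 - p0)
    observed = 0
    pairs = 0
    for group in iter_groups(data):
        umis = sorted(group.umis)
        S = len(umis)
        if S < 2:
            continue
        pairs += S * (S - 1) // 2
        observed += sum(
            1
            for i in range(S)
            for j in range(i + 1, S)
            if hamming(umis[i], umis[j]) == 1
        )
    if pairs == 0:
        raise ValueError("no gene has two or more UMIs; adjacency excess undefined")
    expected = pairs * p_adj_pair
    return observed / expected


def run_report(
    data: Dataset,
    stages: dict | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Machine-readable run summary (JSON-serializable)."""
    df = data.df
    genic = df.loc[~df["intergenic"]] if len(df) else df
    sizes = genic["cb"].value_counts() if len(genic) else pd.Series(dtype=int)
    report = {
        "n_records": int(len(df)),
        "n_cells": int(sizes.size),
        "total_reads": int(df["reads"].sum()) if len(df) else 0,
        "total_molecules": int(len(genic)),
        "umi_length": int(data.umi_length),
        "median_cell_size": float(sizes.median()) if len(sizes) else 0.0,
        "seed": seed,
        "config": config or {},
        "stages": stages or {},
    }
    return json.loads(json.dumps(report))  # guarantee JSON-serializability
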