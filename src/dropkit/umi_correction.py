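"""Removal of erroneous UMIs within each gene of each cell.

A single-base error in a UMI inflates the molecular count by one.  Within a
gene/cell group, a UMI ``u`` at Hamming distance 1 from a better-supported
UMI ``U`` is suspect — but for saturated genes adjacent UMIs also arise by
chance, so simply dropping all of them over-corrects.  The module provides:

* ``cluster_filter`` — drop any UMI with an adjacent UMI of at least as many
  reads (the classical method; ``neq=True`` requires strictly more reads);
* ``directional_filter`` — drop a UMI with an adjacent UMI holding more than
  twice its reads (network method);
* ``bayesian_filter`` — the posterior model.  For each target UMI ``U`` the
  Hamming-1 neighborhood is split into erroneous and real subsets; the
  probability of a split combines (i) base-call quality likelihoods at the
  distinguishing position, (ii) a prior on the number of *real* adjacent
  UMIs derived from a dynamic-programming occupancy model of drawing UMIs
  from the pool, and (iii) a binomial model for the number of *error* reads
  together with a collision correction for error events that land on the
  same sequence.  The maximum a posteriori error count determines which
  UMIs are removed; their reads are reassigned to ``U`` so reads are
  conserved.  Ordering candidates by read count (and quality likelihood
  ratio) reduces the search over splits from 2^|neighborhood| to the nested
  prefixes of that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from dropkit.records import Dataset
from dropkit.umi_distribution import UmiDistribution, estimate_umi_distribution

logger = logging.getLogger("dropkit")

_BASES = "ACGT"

__all__ = [
    "GeneUmiGroup",
    "NeighborhoodView",
    "QualityModel",
    "AdjacencyPrior",
    "ErrorPosterior",
    "hamming",
    "hamming1_variants",
    "p_adjacent",
    "iter_groups",
    "adjacent_umis",
    "cluster_filter",
    "directional_filter",
    "train_quality_model",
    "build_adjacency_prior",
    "real_count_distribution",
    "error_count_distribution",
    "collisions_among_errors",
    "partition_probability",
    "posterior_error_count",
    "bayesian_filter",
]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


def hamming1_variants(umi: str):
    """All 3L sequences at Hamming distance exactly 1."""
    for i, base in enumerate(umi):
        for b in _BASES:
            if b != base:
                yield umi[:i] + b + umi[i + 1 :]


def p_adjacent(umi: str, dist: UmiDistribution) -> float:
    """Probability of drawing a UMI adjacent to ``umi`` from the pool."""
    if dist.uniform:
        return 3 * dist.umi_length / dist.pool_size
    return sum(dist.probability(v) for v in hamming1_variants(umi))


@dataclass
class GeneUmiGroup:
    """All UMIs of one gene in one cell: ``umi -> (reads, quality vector)``."""

    cell: str
    gene: str
    umis: dict  # umi -> (reads, np.ndarray quals)

    @property
    def size(self) -> int:
        return len(self.umis)

    def reads(self, umi: str) -> int:
        return self.umis[umi][0]

    @property
    def total_reads(self) -> int:
        return sum(r for r, _ in self.umis.values())


def iter_groups(data: Dataset):
    """Yield GeneUmiGroup for every (cell, gene) pair, genic records only."""
    df = data.df
    mask = ~df["intergenic"].to_numpy()
    idx = np.flatnonzero(mask)
    sub = df.iloc[idx]
    for (cb, gene), rows in sub.groupby(["cb", "gene"], sort=True).indices.items():
        rows = idx[rows]
        umis = {
            df["umi"].iat[i]: (int(df["reads"].iat[i]), data.quals[i]) for i in rows
        }
        yield GeneUmiGroup(cb, gene, umis)


@dataclass
class NeighborhoodView:
    """Hamming-1 neighborhood of a target UMI within its group.

    ``small`` are neighbors with reads <= R (ties included; the error
    candidates), ``large`` those with more reads than the target.  For each
    small neighbor the distinguishing-position quality (the neighbor's mean
    Phred score at the mismatching base) is recorded.
    """

    target: str
    reads: int  # R
    small: list[str]
    large: list[str]
    small_reads: np.ndarray
    small_quals: np.ndarray  # distinguishing-position quality of each small neighbor

    @property
    def n_s(self) -> int:
        return len(self.small)

    @property
    def n_l(self) -> int:
        return len(self.large)


def adjacent_umis(u: str, group: GeneUmiGroup) -> NeighborhoodView:
    if u not in group.umis:
        raise KeyError(f"UMI {u} not present in group {group.cell}/{group.gene}")
    R = group.reads(u)
    small, large, s_reads, s_quals = [], [], [], []
    for i, base in enumerate(u):
        for b in _BASES:
            if b == base:
                continue
            v = u[:i] + b + u[i + 1 :]
            hit = group.umis.get(v)
            if hit is None:
                continue
            r, q = hit
            if r <= R:
                small.append(v)
                s_reads.append(r)
                s_quals.append(float(q[i]))
            else:
                large.append(v)
    return NeighborhoodView(
        u, R, small, large, np.asarray(s_reads, dtype=int), np.asarray(s_quals)
    )


# ---------------------------------------------------------------------------
# baseline filters
# ---------------------------------------------------------------------------


def cluster_filter(group: GeneUmiGroup, neq: bool = False) -> set[str]:
    """Classical adjacency filter.

    Default mode drops ``u`` when an adjacent UMI has at least as many reads
    (equal-read ties resolved deterministically: the lexicographically
    smaller UMI survives).  ``neq`` mode drops only on strictly larger
    neighbors, so equal-read pairs are both kept.
    """
    kept = set()
    for u, (r, _) in group.umis.items():
        drop = False
        for v in hamming1_variants(u):
            hit = group.umis.get(v)
            if hit is None:
                continue
            rv = hit[0]
            if rv > r or (not neq and rv == r and v < u):
                drop = True
                break
        if not drop:
            kept.add(u)
    return kept


def directional_filter(group: GeneUmiGroup, ratio: float = 2.0) -> set[str]:
    """Drop any UMI with an adjacent UMI holding more than ``ratio`` times
    its reads.

    Removal does not change surviving read counts, so a single evaluation on
    the original group is already the fixpoint of iterating the rule over
    the adjacency network.
    """
    kept = set()
    for u, (r, _) in group.umis.items():
        drop = any(
            (hit := group.umis.get(v)) is not None and hit[0] > ratio * r
            for v in hamming1_variants(u)
        )
        if not drop:
            kept.add(u)
    return kept


# ---------------------------------------------------------------------------
# quality model
# ---------------------------------------------------------------------------


@dataclass
class QualityModel:
    """Quantized distributions of the distinguishing-position quality.

    ``support`` holds at most ``k_q`` representative quality values (merged
    quantiles of the marginal); ``p_q`` is the marginal P(q) over all
    adjacent pairs, ``p_q_err`` the conditional P(q | error) learned from
    two-UMI genes, and ``p_e`` the per-read error rate.
    """

    support: np.ndarray
    p_q: np.ndarray
    p_q_err: np.ndarray
    p_e: float

    def __post_init__(self) -> None:
        for p in (self.p_q, self.p_q_err):
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("quality distributions must sum to 1")
        if not 0.0 < self.p_e < 1.0:
            raise ValueError("per-read error rate must lie in (0, 1)")

    def _bin(self, q) -> np.ndarray:
        return np.argmin(np.abs(np.subtract.outer(np.atleast_1d(q), self.support)), axis=1)

    def marginal(self, q) -> np.ndarray:
        return self.p_q[self._bin(q)]

    def conditional_err(self, q) -> np.ndarray:
        return self.p_q_err[self._bin(q)]

    def likelihood_ratio(self, q) -> np.ndarray:
        """P(q | error) / P(q); larger values are more error-like."""
        b = self._bin(q)
        return self.p_q_err[b] / self.p_q[b]


def _two_umi_pairs(data: Dataset):
    """(adjacent, r, R, q) for genes containing exactly two UMIs.

    The smaller UMI (the putative error for adjacent pairs) is selected by
    ascending reads, then lower quality at the first differing position,
    then lexicographically; ``q`` is its quality at that position.
    Non-adjacent pairs are yielded too: they characterize what *chance*
    co-occurrence looks like in the same gene-size class.
    """
    for group in iter_groups(data):
        if group.size != 2:
            continue
        (u1, (r1, q1)), (u2, (r2, q2)) = sorted(group.umis.items())
        diff = [i for i, (a, b) in enumerate(zip(u1, u2)) if a != b]
        pos = diff[0]
        adjacent = len(diff) == 1
        if (r1, q1[pos], u2) < (r2, q2[pos], u1):
            yield adjacent, r1, r2, float(q1[pos])
        else:
            yield adjacent, r2, r1, float(q2[pos])


def _chance_pair_probability(dist: UmiDistribution) -> float:
    """P(Hamming distance 1 | two distinct independent draws)."""
    p0 = float(np.sum(dist.probs**2))
    p1 = float(
        sum(p * p_adjacent(u, dist) for u, p in zip(dist.sequences, dist.probs))
    )
    return p1 / (1.0 - p0) if p0 < 1.0 else 0.0


def _truncation_corrected_rate(r_bar: float, n_bar: float, p_max: float) -> float:
    """Per-read error rate from the mean error reads of observed pairs.

    Observed pairs condition on at least one error read, so the expected
    count is ``n p / (1 - (1-p)^n)`` rather than ``n p``; invert that for
    ``p``.  When the observed mean is at the truncation floor (r_bar <= 1)
    the rate is unidentifiable from reads and the floor 1e-3 is returned.
    """
    floor = 1e-3
    if n_bar <= 1 or r_bar <= 1.0:
        return floor

    def f(p: float) -> float:
        return n_bar * p / (1.0 - (1.0 - p) ** n_bar) - r_bar

    if f(p_max) <= 0:
        return p_max
    try:
        return float(max(floor, min(brentq(f, 1e-9, p_max), p_max)))
    except ValueError:
        return floor


def train_quality_model(
    data: Dataset, k_q: int = 15, dist: UmiDistribution | None = None
) -> QualityModel:
    """Fit the quality model from genes with exactly two adjacent UMIs.

    The marginal P(q) pools the distinguishing-position qualities of every
    ordered adjacent pair in the dataset, quantized to at most ``k_q``
    support points (uniform quantiles; quantiles closer than 1e-5 merged).
    The conditional P(q | error) uses the smaller UMI of each two-UMI gene;
    the per-read error rate starts from p_E = sum(r) / sum(r + R) over the
    same training genes.

    With a UMI distribution supplied, two corrections are applied, both
    material for shallow, saturated libraries where adjacent pairs are not
    purely errors: (1) the expected number of *chance*-adjacent training
    pairs (from the chance-adjacency probability of the distribution times
    the observed count of non-adjacent two-UMI genes) is subtracted from
    the conditional quality histogram and from the read moments; (2) the
    conditioning of the training set on at least one error read is undone
    by inverting the zero-truncated expectation, so p_E estimates the
    marginal per-read rate the binomial model expects.  Both corrections
    vanish for deep libraries dominated by true errors.
    """
    all_q = []
    for group in iter_groups(data):
        for u in group.umis:
            view = adjacent_umis(u, group)
            all_q.extend(view.small_quals.tolist())
    pairs = list(_two_umi_pairs(data))
    adj = [(r, R, q) for a, r, R, q in pairs if a]
    nonadj = [(r, R, q) for a, r, R, q in pairs if not a]
    if not adj or not all_q:
        raise ValueError(
            "no two-adjacent-UMI training genes found; fall back to the "
            "cluster method for this dataset"
        )
    all_q = np.asarray(all_q)
    qs = np.quantile(all_q, (np.arange(k_q) + 0.5) / k_q)
    support = [qs[0]]
    for v in qs[1:]:
        if v - support[-1] > 1e-5:
            support.append(v)
    support = np.asarray(support)

    def quantize_counts(values: np.ndarray, pseudo: float) -> np.ndarray:
        bins = np.argmin(np.abs(np.subtract.outer(values, support)), axis=1)
        counts = np.bincount(bins, minlength=len(support)).astype(float) + pseudo
        return counts / counts.sum()

    p_q = quantize_counts(all_q, pseudo=0.5)
    err_q = np.asarray([q for _, _, q in adj])
    p_q_err = quantize_counts(err_q, pseudo=0.5)
    r_sum = float(sum(r for r, _, _ in adj))
    n_sum = float(sum(r + R for r, R, _ in adj))
    p_e = r_sum / n_sum

    if dist is not None and nonadj:
        p_pair = _chance_pair_probability(dist)
        n_chance = min(len(nonadj) * p_pair / max(1.0 - p_pair, 1e-9), 0.9 * len(adj))
        if n_chance > 0:
            w = n_chance / len(adj)
            p_q_err = np.maximum(p_q_err - w * p_q, 1e-4)
            p_q_err = p_q_err / p_q_err.sum()
            r_null = float(np.mean([r for r, _, _ in nonadj]))
            n_null = float(np.mean([r + R for r, R, _ in nonadj]))
            r_sum = max(r_sum - n_chance * r_null, 0.0)
            n_sum = max(n_sum - n_chance * n_null, 1.0)
        if n_chance > 0.5 * len(adj):
            # chance pairs dominate the training set (short / saturated
            # UMIs): the read moments carry no error signal, so use the
            # conservative floor rather than a noise-driven estimate
            p_e = 1e-3
        else:
            n_eff = max(len(adj) - n_chance, 1.0)
            p_e = _truncation_corrected_rate(r_sum / n_eff, n_sum / n_eff, p_max=p_e)

    return QualityModel(support, p_q, p_q_err, p_e)


# ---------------------------------------------------------------------------
# adjacency prior (dynamic programming occupancy model)
# ---------------------------------------------------------------------------


class AdjacencyPrior:
    """Distributions of the number of distinct adjacent UMIs after ``s``
    draws from the pool.

    State ``(k, s)``: after picking ``s`` UMIs, ``k`` of the ``K = 3L``
    possible adjacent sequences have been seen.  Transition from
    ``(k, s-1)`` stays with probability ``1 - p_adj (K-k)/K`` and moves to
    ``(k+1, s)`` with probability ``p_adj (K-k)/K``.  Tables are quantized
    over ``p_adj`` with step ``dp_step`` and cached; columns are indexed by
    the number of picks ``s`` (so the gene-size column is ``S_g - 1`` picks,
    the target UMI itself not being a draw).
    """

    def __init__(self, umi_length: int, dp_step: float = 0.01, s_max: int = 64):
        self.K = 3 * umi_length
        self.dp_step = float(dp_step)
        self.s_max = int(s_max)
        self._cache: dict[int, np.ndarray] = {}

    def quantize(self, p_adj: float) -> int:
        n_bins = int(round(1.0 / self.dp_step))
        q = int(round(p_adj / self.dp_step))
        return min(max(q, 1), n_bins)  # p_adj = 0 maps to the smallest bin

    def _build(self, q: int, s_max: int) -> np.ndarray:
        p = q * self.dp_step
        K = self.K
        T = np.zeros((K + 1, s_max + 1))
        T[0, 0] = 1.0
        ks = np.arange(K + 1)
        stay = 1.0 - p * (K - ks) / K
        move = p * (K - ks[:-1]) / K  # from state k to k+1
        for s in range(1, s_max + 1):
            T[:, s] = T[:, s - 1] * stay
            T[1:, s] += T[:-1, s - 1] * move
        return T

    def table(self, p_adj: float, picks: int) -> np.ndarray:
        """P(N' = k | picks) as a vector over k = 0..K."""
        q = self.quantize(p_adj)
        cached = self._cache.get(q)
        if cached is None or cached.shape[1] <= picks:
            target = max(picks, self.s_max)
            cached = self._build(q, target)
            self._cache[q] = cached
        return cached[:, picks]

    def tail(self, p_adj: float, picks: int) -> np.ndarray:
        """P(N' >= k | picks) over k = 0..K."""
        pmf = self.table(p_adj, picks)
        return np.cumsum(pmf[::-1])[::-1]


def build_adjacency_prior(
    s_max: int, umi_length: int, dp_step: float = 0.01
) -> AdjacencyPrior:
    return AdjacencyPrior(umi_length, dp_step=dp_step, s_max=s_max)


def real_count_distribution(
    n_s: int,
    n_l: int,
    s_g: int,
    p_adj: float,
    prior: AdjacencyPrior,
) -> np.ndarray:
    """Distribution of the number of real UMIs among the small candidates.

    ``P(#Real >= n) = P(N' >= n + N_L | N' >= N_L)`` read from the
    occupancy prior at ``S_g - 1`` picks, converted to a mass function and
    renormalized over the support ``0..N_S`` (conditioning constants cancel
    in that renormalization, leaving ``P(#Real = n) ∝ P(N' = n + N_L)``).
    """
    if n_s == 0:
        return np.array([1.0])
    picks = max(s_g - 1, 0)
    pmf = prior.table(p_adj, picks)
    w = np.zeros(n_s + 1)
    for n in range(n_s + 1):
        if n + n_l <= prior.K:
            w[n] = pmf[n + n_l]
    total = w.sum()
    if total <= 0:
        # the prior carries no mass on the observed configuration (e.g. more
        # neighbors than the occupancy model allows); fall back to uniform
        return np.full(n_s + 1, 1.0 / (n_s + 1))
    return w / total


def error_count_distribution(
    ordered_reads: np.ndarray, R: int, p_e: float
) -> np.ndarray:
    """Distribution of the total error count over nested candidate prefixes.

    ``ordered_reads`` lists the small candidates in search order.  For a
    prefix of ``i`` candidates, the total error reads are ``r_E(i) =``
    cumulative reads of the first ``i``; the weight is the binomial mass
    ``Binom(r_E(i); n = R + r_E(i), p_E)`` (for ``i = 0`` the mass of zero
    error reads in ``R`` trials), normalized over ``i = 0..N_S``.
    """
    if not 0.0 < p_e < 1.0:
        raise ValueError("per-read error rate must lie in (0, 1)")
    ordered_reads = np.asarray(ordered_reads, dtype=int)
    r_cum = np.concatenate([[0], np.cumsum(ordered_reads)])
    w = stats.binom.pmf(r_cum, R + r_cum, p_e)
    total = w.sum()
    if total <= 0:
        out = np.zeros(len(w))
        out[0] = 1.0
        return out
    return w / total


def collisions_among_errors(
    observed_errors: int, total_errors: int, prior: AdjacencyPrior
) -> float:
    """Probability that ``total_errors`` error events yield exactly
    ``observed_errors`` distinct sequences.

    The same occupancy chain as the adjacency prior, with adjacency
    probability 1 (every error lands on one of the K neighboring sequences):
    ``p(#Collisions = total - observed) = p(N' = observed | picks = total)``.
    """
    if observed_errors > total_errors:
        raise ValueError("observed errors cannot exceed total errors")
    if total_errors == 0:
        return 1.0 if observed_errors == 0 else 0.0
    if observed_errors > prior.K:
        return 0.0
    pmf = prior.table(1.0, total_errors)
    return float(pmf[observed_errors])


# ---------------------------------------------------------------------------
# posterior over splits
# ---------------------------------------------------------------------------


def partition_probability(
    view: NeighborhoodView,
    err_idx: np.ndarray,
    qm: QualityModel,
    prior: AdjacencyPrior,
    p_adj: float,
    err_dist: np.ndarray | None = None,
) -> float:
    """Unnormalized probability of one split of the small candidates.

    ``err_idx`` indexes the candidates assigned to the error side; the rest
    (plus all larger neighbors) are treated as real.  Factors: quality
    likelihoods, the real-count prior at the size of the real side, and the
    error-count distribution summed over unobserved (collided) errors.
    """
    err_idx = np.asarray(err_idx, dtype=int)
    n_s = view.n_s
    keep_mask = np.ones(n_s, dtype=bool)
    keep_mask[err_idx] = False
    q_err = view.small_quals[err_idx]
    q_keep = view.small_quals[keep_mask]
    p = float(np.prod(qm.conditional_err(q_err))) * float(np.prod(qm.marginal(q_keep)))
    s_g = n_s + view.n_l + 1  # group size seen by this target
    real_pmf = real_count_distribution(n_s, view.n_l, s_g, p_adj, prior)
    p *= real_pmf[int(keep_mask.sum())]
    if err_dist is None:
        order = search_order(view, qm)
        err_dist = error_count_distribution(view.small_reads[order], view.reads, qm.p_e)
    j = len(err_idx)
    tail = sum(
        collisions_among_errors(j, i, prior) * err_dist[i] for i in range(j, len(err_dist))
    )
    return p * tail


@dataclass
class ErrorPosterior:
    """Posterior over the number of erroneous UMIs in a neighborhood."""

    candidates: list[str]  # search order: most error-like first
    probs: np.ndarray  # p(#Errors = j), j = 0..N_S
    map_count: int

    @property
    def map_prefix(self) -> list[str]:
        return self.candidates[: self.map_count]


def search_order(view: NeighborhoodView, qm: QualityModel) -> np.ndarray:
    """Candidate order for the nested-split search: ascending reads, then
    descending quality likelihood ratio (most error-like first), then
    lexicographic for determinism."""
    lr = qm.likelihood_ratio(view.small_quals)
    keys = list(zip(view.small_reads.tolist(), (-lr).tolist(), view.small))
    return np.array(sorted(range(view.n_s), key=lambda i: keys[i]), dtype=int)


def posterior_error_count(
    view: NeighborhoodView,
    qm: QualityModel,
    prior: AdjacencyPrior,
    p_adj: float,
) -> ErrorPosterior:
    """Evaluate the posterior on the nested splits of the search order."""
    if view.n_s == 0:
        return ErrorPosterior([], np.array([1.0]), 0)
    order = search_order(view, qm)
    ordered = [view.small[i] for i in order]
    reads = view.small_reads[order]
    err_dist = error_count_distribution(reads, view.reads, qm.p_e)
    weights = np.array(
        [
            partition_probability(view, order[:j], qm, prior, p_adj, err_dist=err_dist)
            for j in range(view.n_s + 1)
        ]
    )
    total = weights.sum()
    probs = weights / total if total > 0 else np.full(len(weights), 1.0 / len(weights))
    map_count = int(np.argmax(probs))
    return ErrorPosterior(ordered, probs, map_count)


# ---------------------------------------------------------------------------
# filters over a whole dataset
# ---------------------------------------------------------------------------


def _rebuild(data: Dataset, new_umis: dict, new_reads: dict) -> Dataset:
    """Apply per-(cb, gene) kept-UMI maps back onto the dataset."""
    df = data.df
    keep_rows, reads_out = [], []
    for i in range(len(df)):
        key = (df["cb"].iat[i], df["gene"].iat[i])
        if df["intergenic"].iat[i] or key not in new_umis:
            keep_rows.append(i)
            reads_out.append(int(df["reads"].iat[i]))
            continue
        umi = df["umi"].iat[i]
        if umi in new_umis[key]:
            keep_rows.append(i)
            reads_out.append(new_reads[key][umi])
    out = df.iloc[keep_rows].copy().reset_index(drop=True)
    out["reads"] = reads_out
    return Dataset(out, data.quals[keep_rows], data.umi_length, aggregate=False)


def apply_group_filter(data: Dataset, keep_fn) -> Dataset:
    """Run a per-group filter; removed UMIs' reads are reassigned to the
    dominating adjacent UMI, following chains to a survivor, so reads are
    conserved."""
    new_umis, new_reads = {}, {}
    for group in iter_groups(data):
        kept = keep_fn(group)
        reads = {u: group.reads(u) for u in kept}
        for u, (r, _) in group.umis.items():
            if u in kept:
                continue
            target = _absorbing_survivor(u, kept, group)
            if target is not None:
                reads[target] += r
        new_umis[(group.cell, group.gene)] = kept
        new_reads[(group.cell, group.gene)] = reads
    return _rebuild(data, new_umis, new_reads)


def _absorbing_survivor(u: str, kept: set[str], group: GeneUmiGroup) -> str | None:
    """Kept UMI absorbing ``u``'s reads: step to the heaviest adjacent UMI
    (ties to the lexicographically smaller) until a survivor is reached.

    Each step strictly increases (reads, -lex), so the walk terminates; a
    dropped UMI always has a dominating neighbor under the cluster and
    directional rules, hence the walk ends at a kept UMI.
    """
    seen = {u}
    cur = u
    while cur not in kept:
        best = None
        for v in hamming1_variants(cur):
            if v in seen or v not in group.umis:
                continue
            if (group.reads(v), _lex_lo(v)) <= (group.reads(cur), _lex_lo(cur)):
                continue
            if best is None or (group.reads(v), _lex_lo(v)) > (group.reads(best), _lex_lo(best)):
                best = v
        if best is None:
            # no dominating neighbor (shouldn't happen for the built-in
            # rules); fall back to any kept neighbor, else drop the reads
            for v in hamming1_variants(cur):
                if v in kept:
                    return v
            return None
        seen.add(best)
        cur = best
    return cur


def _lex_lo(u: str):
    # invert lexicographic order so max() prefers the smaller sequence on ties
    return tuple(-ord(c) for c in u)


def bayesian_filter(
    data: Dataset,
    dist: UmiDistribution,
    qm: QualityModel | None = None,
    prior: AdjacencyPrior | None = None,
    max_iterations: int = 10,
    collect_audit: bool = False,
) -> tuple[Dataset, pd.DataFrame]:
    """Iterative Bayesian removal of erroneous UMIs.

    Per cell and gene, target UMIs are processed in descending read order;
    for each, the MAP error prefix of its neighborhood posterior is deleted
    and its reads reassigned to the target.  Group statistics are recomputed
    and the pass repeats until no deletion occurs or ``max_iterations`` is
    reached (convergence is typically immediate for small genes).
    """
    if qm is None:
        qm = train_quality_model(data, dist=dist)
    if prior is None:
        prior = AdjacencyPrior(data.umi_length)
    audit = []
    new_umis, new_reads = {}, {}
    for group in iter_groups(data):
        umis = {u: [r, q] for u, (r, q) in group.umis.items()}
        for it in range(max_iterations):
            removed_any = False
            targets = sorted(umis, key=lambda u: (-umis[u][0], u))
            for u in targets:
                if u not in umis:
                    continue
                g = GeneUmiGroup(group.cell, group.gene, {k: (v[0], v[1]) for k, v in umis.items()})
                view = adjacent_umis(u, g)
                if view.n_s == 0:
                    continue
                pa = p_adjacent(u, dist)
                post = posterior_error_count(view, qm, prior, pa)
                for victim in post.map_prefix:
                    if victim not in umis or victim == u:
                        continue
                    umis[u][0] += umis[victim][0]
                    del umis[victim]
                    removed_any = True
                    if collect_audit:
                        audit.append(
                            {
                                "cell": group.cell,
                                "gene": group.gene,
                                "removed_umi": victim,
                                "target_umi": u,
                                "posterior": float(post.probs[post.map_count]),
                                "method": "bayesian",
                            }
                        )
            if not removed_any:
                break
        else:
            logger.warning(
                "bayesian filter did not converge for %s/%s within %d iterations",
                group.cell,
                group.gene,
                max_iterations,
            )
        new_umis[(group.cell, group.gene)] = set(umis)
        new_reads[(group.cell, group.gene)] = {u: v[0] for u, v in umis.items()}
    out = _rebuild(data, new_umis, new_reads)
    return out, pd.DataFrame(
        audit, columns=["cell", "gene", "removed_umi", "target_umi", "posterior", "method"]
    )


def filter_dataset(
    data: Dataset,
    method: str,
    dist: UmiDistribution | None = None,
    **kwargs,
) -> Dataset:
    """Dispatch a UMI correction method over the dataset.

    ``method`` is one of ``none``, ``cluster``, ``cluster-neq``,
    ``directional``, ``bayesian``.
    """
    if method == "none":
        return data
    if method == "cluster":
        return apply_group_filter(data, lambda g: cluster_filter(g, neq=False))
    if method == "cluster-neq":
        return apply_group_filter(data, lambda g: cluster_filter(g, neq=True))
    if method == "directional":
        return apply_group_filter(data, directional_filter)
    if method == "bayesian":
        if dist is None:
            dist = estimate_umi_distribution(data)
        return bayesian_filter(data, dist, **kwargs)[0]
    raise ValueError(f"unknown UMI correction method {method!r}")
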