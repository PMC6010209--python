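"""Empirical UMI frequency distribution and collision correction.

With a limited UMI pool, two molecules of the same gene in the same cell can
receive the same UMI ("collision"), deflating distinct-UMI counts.  Under a
uniform pool of size ``m`` the expected number of distinct UMIs for ``n``
molecules is ``k = m(1 - e^(-n/m))``, inverted as ``n = -m ln(1 - k/m)``.
Droplet libraries, however, show heavily skewed UMI usage, which shrinks the
effective pool; the collision table here inverts the expected-distinct curve
of the *empirical* distribution instead.

The stepwise estimator starts at ``n(1) = 1`` and, for each additional
distinct UMI, adds the expected number of draws until a new distinct one is
seen, ``1 / p(u' not in G_k)`` with ``p(u' not in G_k) = sum_i p_i
(1 - p_i)^n``.  That increment is a first-order (Newton) step on the
expected-distinct equation ``E[k | n] = sum_i (1 - (1 - p_i)^n) = k``; the
implementation refines each step to convergence, so the table is the exact
inverse of the expected-distinct curve rather than its unit-step Euler
approximation (which degrades noticeably for small pools).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dropkit.records import CountMatrix, Dataset

__all__ = [
    "UmiDistribution",
    "CollisionTable",
    "estimate_umi_distribution",
    "collisions_uniform",
    "new_umi_probability",
    "build_collision_table",
    "adjust_counts",
]


@dataclass
class UmiDistribution:
    """Probabilities over the UMI pool.

    ``sequences``/``probs`` hold the support (UMIs with nonzero probability);
    ``pool_size`` is the support size for the empirical model and ``4**L``
    for the uniform comparator.
    """

    sequences: list[str]
    probs: np.ndarray
    umi_length: int
    uniform: bool = False
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.sequences) != len(self.probs):
            raise ValueError("sequences and probabilities are misaligned")
        if not self.uniform:
            if abs(self.probs.sum() - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")
            if len(self.probs) and self.probs.min() <= 0:
                raise ValueError("support probabilities must be positive")
        self._index = {u: i for i, u in enumerate(self.sequences)}

    @property
    def pool_size(self) -> int:
        return 4**self.umi_length if self.uniform else len(self.sequences)

    @classmethod
    def uniform_pool(cls, umi_length: int) -> "UmiDistribution":
        m = 4**umi_length
        # uniform support is represented implicitly; sequences are not
        # enumerated to keep long UMIs tractable
        return cls([], np.array([]), umi_length, uniform=True)

    def probability(self, umi: str) -> float:
        if self.uniform:
            return 1.0 / self.pool_size
        i = self._index.get(umi)
        return 0.0 if i is None else float(self.probs[i])

    def support_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique probability values and their multiplicities.

        Collapsing ties keeps expected-distinct evaluations O(#unique) — for
        the uniform pool a single value of multiplicity ``4**L``.
        """
        if self.uniform:
            m = self.pool_size
            return np.array([1.0 / m]), np.array([m], dtype=float)
        vals, counts = np.unique(self.probs, return_counts=True)
        return vals, counts.astype(float)


def estimate_umi_distribution(data: Dataset) -> UmiDistribution:
    """Empirical UMI probabilities: occurrences across all cell-gene molecules
    divided by total molecules."""
    if not len(data):
        raise ValueError("cannot estimate a UMI distribution from an empty dataset")
    counts = data.df["umi"].value_counts().sort_index()
    probs = counts.to_numpy(dtype=float) / counts.sum()
    return UmiDistribution(list(counts.index), probs, data.umi_length)


def collisions_uniform(k: float, m: int, negligible: float = 0.01) -> float:
    """Uniform-pool collision adjustment ``n = -m ln(1 - k/m)``.

    Returns ``k`` unchanged when ``k/m`` is below ``negligible`` (the
    correction is vanishing there and skipping it avoids numerical noise).
    """
    if k >= m:
        raise ValueError(f"saturated pool: k={k} >= m={m}, inverse undefined")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k / m < negligible:
        return float(k)
    return float(-m * np.log1p(-k / m))


def new_umi_probability(dist: UmiDistribution, n: float) -> float:
    """Probability that the next molecule carries a not-yet-seen UMI after
    ``n`` molecules: ``sum_i p_i (1 - p_i)^n``."""
    if n < 0:
        raise ValueError("n must be non-negative")
    vals, counts = dist.support_probs()
    return float(np.sum(counts * vals * np.exp(n * np.log1p(-vals))))


@dataclass
class CollisionTable:
    """Estimated true molecule count ``n(k)`` for ``k`` observed distinct UMIs.

    Strictly increasing, with ``n(1) = 1`` under any distribution.
    ``lookup`` maps observed counts (0 allowed) to adjusted counts.
    """

    n_of_k: np.ndarray  # n_of_k[k-1] = n(k)
    pool_size: int

    def __post_init__(self) -> None:
        self.n_of_k = np.asarray(self.n_of_k, dtype=float)
        if len(self.n_of_k) and np.any(np.diff(self.n_of_k) <= 0):
            raise ValueError("collision table must be strictly increasing")

    @property
    def max_k(self) -> int:
        return len(self.n_of_k)

    def lookup(self, k: int) -> float:
        if k == 0:
            return 0.0
        if k > self.max_k:
            raise ValueError(
                f"observed {k} distinct UMIs but table covers only k <= {self.max_k}; "
                "extend the table (larger max_k / increment cap)"
            )
        return float(self.n_of_k[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(1, self.max_k + 1), "n_of_k": self.n_of_k}
        )


def build_collision_table(
    dist: UmiDistribution,
    max_k: int | None = None,
    increment_cap: float = 1e5,
    tol: float = 1e-9,
) -> CollisionTable:
    """Stepwise collision table for an arbitrary UMI distribution.

    For each ``k`` the true molecule estimate solves ``sum_i (1-(1-p_i)^n)
    = k``; the step from ``n(k)`` uses the expected draws to a new distinct
    UMI, ``1/p(u' not in G_k)``, as predictor and Newton iterations as
    corrector.  The table stops at ``k = m - 1`` (the inverse is undefined at
    saturation) or when the increment exceeds ``increment_cap``.
    """
    m = dist.pool_size
    vals, counts = dist.support_probs()
    log1m = np.log1p(-vals)

    def expected_distinct(n: float) -> tuple[float, float]:
        surv = np.exp(n * log1m)  # (1-p_i)^n per unique value
        e = float(np.sum(counts * (1.0 - surv)))
        de = float(-np.sum(counts * log1m * surv))
        return e, de

    limit = m - 1 if max_k is None else min(max_k, m - 1)
    out = np.empty(limit)
    n = 1.0
    out[0] = 1.0
    k_done = 1
    for k in range(2, limit + 1):
        p_new = float(np.sum(counts * vals * np.exp(n * log1m)))
        step = 1.0 / p_new if p_new > 0 else np.inf
        if not np.isfinite(step) or step > increment_cap:
            break
        n_next = n + step
        for _ in range(60):
            e, de = expected_distinct(n_next)
            if abs(e - k) < tol or de <= 0:
                break
            n_next -= (e - k) / de
        if n_next <= n:  # monotonicity guard for degenerate numerics
            n_next = n + max(step, tol)
        n = n_next
        out[k - 1] = n
        k_done = k
    return CollisionTable(out[:k_done], m)


def adjust_counts(matrix: CountMatrix, table: CollisionTable) -> CountMatrix:
    """Replace each distinct-UMI count ``k`` by the collision-adjusted
    ``n(k)``; zeros are untouched."""
    vals = matrix.values.tocoo(copy=True)
    vals.data = np.array([table.lookup(int(round(k))) for k in vals.data])
    return CountMatrix(list(matrix.genes), list(matrix.cells), vals.tocsr())
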