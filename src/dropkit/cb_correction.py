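"""Merging of cellular barcodes split by sequence errors.

A sequence error in a cellular barcode (CB) routes part of a droplet's reads
to a spurious child barcode at small Hamming distance from the parent.
Because reads per UMI are generally above one, the child ends up sharing
gene-UMI combinations with the parent — something two independent cells
almost never do.  The Poisson merge test exploits this: the observed
composition overlap ``C_ij = sum_g |S_i,g ∩ S_j,g|`` is compared against its
expectation under independence,

    EC_ij = sum_g sum_u (1 - (1-p(u))^{S'_i,g}) (1 - (1-p(u))^{S'_j,g}),

where ``p(u)`` is the empirical UMI distribution and ``S'`` are
collision-adjusted set sizes.  ``C_ij`` is modelled as Poisson(EC_ij) and a
small tail probability (after Bonferroni over a barcode's candidate
targets) triggers the merge.  Baselines: ``merge_simple`` (merge into any
larger CB within the Hamming radius) and ``merge_known_barcodes``
(reassignment onto a whitelist).  A two-species audit quantifies wrong
merges when gene labels carry an organism tag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dropkit.records import Dataset
from dropkit.umi_distribution import CollisionTable, UmiDistribution

logger = logging.getLogger("dropkit")

_BASES = "ACGT"

__all__ = [
    "CellComposition",
    "MergePlan",
    "build_compositions",
    "observed_intersection",
    "expected_intersection",
    "poisson_merge_test",
    "merge_poisson",
    "merge_simple",
    "merge_known_barcodes",
    "apply_merge",
    "cross_species_merge_audit",
]


@dataclass
class CellComposition:
    """Per-cell molecular composition: gene -> set of UMIs."""

    cb: str
    genes: dict  # gene -> frozenset of UMIs

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.genes.values())


def build_compositions(data: Dataset) -> dict[str, CellComposition]:
    comps: dict[str, dict] = {}
    df = data.df
    for cb, umi, gene, inter in zip(df["cb"], df["umi"], df["gene"], df["intergenic"]):
        if inter:
            continue
        comps.setdefault(cb, {}).setdefault(gene, set()).add(umi)
    return {
        cb: CellComposition(cb, {g: frozenset(s) for g, s in genes.items()})
        for cb, genes in comps.items()
    }


def observed_intersection(a: CellComposition, b: CellComposition) -> int:
    """Number of shared gene-UMI pairs."""
    total = 0
    small, big = (a, b) if len(a.genes) <= len(b.genes) else (b, a)
    for gene, umis in small.genes.items():
        other = big.genes.get(gene)
        if other:
            total += len(umis & other)
    return total


class _ExpectedIntersection:
    """Memoized per-gene expected overlap as a function of the two
    collision-adjusted set sizes (the expectation depends on the sizes
    only, so each (S_i, S_j) pair is computed once)."""

    def __init__(self, dist: UmiDistribution, table: CollisionTable | None):
        vals, counts = dist.support_probs()
        self._p = vals
        self._w = counts
        self._table = table
        self._cache: dict[tuple[float, float], float] = {}

    def adjusted(self, size: int) -> float:
        if self._table is None:
            return float(size)
        k = min(size, self._table.max_k)
        return self._table.lookup(k)

    def gene_expectation(self, size_a: int, size_b: int) -> float:
        sa, sb = self.adjusted(size_a), self.adjusted(size_b)
        if sa > sb:
            sa, sb = sb, sa
        key = (sa, sb)
        hit = self._cache.get(key)
        if hit is None:
            one_minus = np.log1p(-self._p)
            hit = float(
                np.sum(
                    self._w
                    * (1.0 - np.exp(sa * one_minus))
                    * (1.0 - np.exp(sb * one_minus))
                )
            )
            self._cache[key] = hit
        return hit


def expected_intersection(
    a: CellComposition,
    b: CellComposition,
    dist: UmiDistribution,
    table: CollisionTable | None = None,
    _memo: _ExpectedIntersection | None = None,
) -> float:
    """Expected number of shared gene-UMI pairs for independent cells."""
    memo = _memo if _memo is not None else _ExpectedIntersection(dist, table)
    total = 0.0
    small, big = (a, b) if len(a.genes) <= len(b.genes) else (b, a)
    for gene, umis in small.genes.items():
        other = big.genes.get(gene)
        if other:
            total += memo.gene_expectation(len(umis), len(other))
    return total


def poisson_merge_test(C: int, EC: float) -> float:
    """Tail probability P(X >= C) for X ~ Poisson(EC); C = 0 gives 1."""
    if EC < 0:
        raise ValueError("expected intersection must be non-negative")
    if C <= 0:
        return 1.0
    return float(stats.poisson.sf(C - 1, EC))


@dataclass
class MergePlan:
    """Forest of merges: source CB -> target CB plus per-pair statistics."""

    targets: dict = field(default_factory=dict)  # source -> target
    stats: pd.DataFrame | None = None
    method: str = "none"

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def dropped(self) -> set[str]:
        return {s for s, t in self.targets.items() if t is None}

    def to_frame(self) -> pd.DataFrame:
        if self.stats is not None:
            return self.stats
        return pd.DataFrame(
            [(s, t) for s, t in self.targets.items()], columns=["source", "target"]
        )


def _hamming_neighbors(cb: str, universe: set[str], max_hamming: int) -> set[str]:
    """Deterministic enumeration of sequences within the Hamming radius that
    exist in ``universe`` (cheaper than an all-pairs scan)."""
    found = set()
    positions = range(len(cb))
    for dist_ in range(1, max_hamming + 1):
        for pos_combo in itertools.combinations(positions, dist_):
            for subs in itertools.product(_BASES, repeat=dist_):
                if any(cb[p] == s for p, s in zip(pos_combo, subs)):
                    continue
                cand = list(cb)
                for p, s in zip(pos_combo, subs):
                    cand[p] = s
                cand = "".join(cand)
                if cand in universe:
                    found.add(cand)
    return found


def _redirect(targets: dict, source: str, target: str) -> None:
    """Record source -> target keeping the plan a forest (path compression:
    anything already pointing at ``source`` is rerouted to ``target``)."""
    targets[source] = target
    for s, t in targets.items():
        if t == source:
            targets[s] = target


def merge_poisson(
    cells: dict[str, CellComposition],
    dist: UmiDistribution,
    table: CollisionTable | None = None,
    max_hamming: int = 2,
    alpha: float = 0.01,
) -> MergePlan:
    """Composition-overlap merge.

    Each CB is compared against candidates with at least as many molecules
    and CB Hamming distance <= ``max_hamming``; the Poisson tail p-value is
    Bonferroni-adjusted by the candidate count and the source merges into
    the candidate with the smallest adjusted p-value when it falls below
    ``alpha``.  Sources are processed small to large in one pass.
    """
    memo = _ExpectedIntersection(dist, table)
    sizes = {cb: c.size for cb, c in cells.items()}
    by_len: dict[int, set[str]] = {}
    for cb in cells:
        by_len.setdefault(len(cb), set()).add(cb)
    order = sorted(cells, key=lambda cb: (sizes[cb], cb))
    targets: dict[str, str] = {}
    rows = []
    for cb in order:
        universe = by_len[len(cb)]
        neighbors = _hamming_neighbors(cb, universe, max_hamming)
        cands = sorted(
            c
            for c in neighbors
            if c not in targets
            and (sizes[c] > sizes[cb] or (sizes[c] == sizes[cb] and c < cb))
        )
        if not cands:
            continue
        best = None
        for cand in cands:
            C = observed_intersection(cells[cb], cells[cand])
            EC = expected_intersection(cells[cb], cells[cand], dist, table, _memo=memo)
            p_raw = poisson_merge_test(C, EC)
            p_adj = min(1.0, p_raw * len(cands))
            rows.append((cb, cand, C, EC, p_raw, p_adj, "poisson"))
            if p_adj < alpha and (
                best is None
                or p_adj < best[1]
                or (p_adj == best[1] and sizes[cand] > sizes[best[0]])
            ):
                best = (cand, p_adj)
        if best is not None:
            _redirect(targets, cb, best[0])
    return MergePlan(
        targets,
        pd.DataFrame(
            rows, columns=["source", "target", "C", "EC", "p_raw", "p_adj", "method"]
        ),
        "poisson",
    )


def merge_simple(
    cells: dict[str, CellComposition], max_hamming: int = 2
) -> MergePlan:
    """Merge every CB into its largest strictly-bigger neighbor within the
    Hamming radius (ties broken lexicographically)."""
    sizes = {cb: c.size for cb, c in cells.items()}
    by_len: dict[int, set[str]] = {}
    for cb in cells:
        by_len.setdefault(len(cb), set()).add(cb)
    targets: dict[str, str] = {}
    for cb in sorted(cells, key=lambda c: (sizes[c], c)):
        neighbors = _hamming_neighbors(cb, by_len[len(cb)], max_hamming)
        bigger = [c for c in neighbors if sizes[c] > sizes[cb] and c not in targets]
        if bigger:
            target = max(bigger, key=lambda c: (sizes[c], [-ord(x) for x in c]))
            _redirect(targets, cb, target)
    return MergePlan(targets, None, "simple")


def merge_known_barcodes(
    cells: dict[str, CellComposition],
    whitelist: list[str],
    dist: UmiDistribution | None = None,
    table: CollisionTable | None = None,
    max_hamming: int = 2,
) -> MergePlan:
    """Reassign non-whitelist CBs to the nearest valid CB.

    The valid CB must hold at least as many molecules; equidistant multiple
    matches are resolved by the composition test when a UMI distribution is
    supplied, else by larger size then lexicographic order.  CBs farther
    than ``max_hamming`` from every valid CB are dropped (target ``None``).
    """
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    valid = set(whitelist)
    sizes = {cb: c.size for cb, c in cells.items()}
    memo = _ExpectedIntersection(dist, table) if dist is not None else None
    targets: dict[str, str | None] = {}
    for cb in sorted(cells, key=lambda c: (sizes[c], c)):
        if cb in valid:
            continue
        cand_by_dist: list[list[str]] = []
        matches: list[str] = []
        for d in range(1, max_hamming + 1):
            hits = sorted(
                c
                for c in _hamming_neighbors(cb, valid, d)
                if sizes.get(c, 0) >= sizes[cb] and c in cells
            )
            hits = [c for c in hits if all(c not in lvl for lvl in cand_by_dist)]
            cand_by_dist.append(hits)
            if hits:
                matches = hits
                break
        if not matches:
            targets[cb] = None
            continue
        if len(matches) == 1 or memo is None:
            target = max(matches, key=lambda c: (sizes[c], [-ord(x) for x in c]))
        else:
            def p_adj_of(c):
                C = observed_intersection(cells[cb], cells[c])
                EC = expected_intersection(cells[cb], cells[c], dist, table, _memo=memo)
                return poisson_merge_test(C, EC)
            target = min(matches, key=lambda c: (p_adj_of(c), -sizes[c], c))
        _redirect(targets, cb, target)
    return MergePlan(targets, None, "known")


def apply_merge(data: Dataset, plan: MergePlan) -> Dataset:
    """Relabel records according to the plan; duplicate (cb, umi, gene) keys
    aggregate, so molecule sets union and total reads are conserved (except
    for whitelist rejects, which are removed)."""
    for s, t in plan.targets.items():
        if t is not None and t in plan.targets and plan.targets[t] is not None:
            raise ValueError(f"cyclic/chained merge plan at {s} -> {t}")
    df = data.df
    drop = plan.dropped
    keep = ~df["cb"].isin(drop).to_numpy()
    idx = np.flatnonzero(keep)
    sub = df.iloc[idx].copy()
    mapping = {s: t for s, t in plan.targets.items() if t is not None}
    sub["cb"] = [mapping.get(cb, cb) for cb in sub["cb"]]
    return Dataset(sub.reset_index(drop=True), data.quals[idx], data.umi_length)


def cross_species_merge_audit(
    plan: MergePlan,
    data: Dataset,
    species_of_gene: dict[str, str],
    min_genes: int = 20,
    n_real: int = 100,
    reference_plan: MergePlan | None = None,
) -> dict:
    """Audit merges on a two-species mixture.

    Cells with fewer than ``min_genes`` expressed genes are ignored; each
    remaining cell is assigned the species with more molecules; the
    ``n_real`` largest cells count as real.  Reported: total merges, merges
    into real cells, the fraction of those crossing species, and (when a
    reference plan is given) the fraction of merge decisions agreeing with
    it.
    """
    df = data.df.loc[~data.df["intergenic"]]
    genes_per_cell = df.groupby("cb")["gene"].nunique()
    eligible = set(genes_per_cell.index[genes_per_cell >= min_genes])
    species_counts = (
        df.assign(sp=[species_of_gene.get(g, "?") for g in df["gene"]])
        .groupby(["cb", "sp"])
        .size()
        .unstack(fill_value=0)
    )
    species = species_counts.idxmax(axis=1)
    sizes = df.groupby("cb").size()
    real = set(sorted(eligible, key=lambda c: (-sizes.get(c, 0), c))[:n_real])
    merges = [
        (s, t)
        for s, t in plan.targets.items()
        if t is not None and s in eligible
    ]
    to_real = [(s, t) for s, t in merges if t in real]
    mixed = [
        (s, t)
        for s, t in to_real
        if s in species.index and t in species.index and species[s] != species[t]
    ]
    agreement = None
    if reference_plan is not None:
        ref = {s: t for s, t in reference_plan.targets.items() if t is not None}
        joint = [s for s, _ in merges if s in ref]
        if joint:
            agreement = float(
                np.mean([dict(merges)[s] == ref[s] for s in joint])
            )
    return {
        "n_merges": len(merges),
        "n_merges_to_real": len(to_real),
        "mixed_fraction": (len(mixed) / len(to_real)) if to_real else 0.0,
        "agreement_with_reference": agreement,
        "method": plan.method,
    }
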