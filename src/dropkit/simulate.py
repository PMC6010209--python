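"""Synthetic droplet-library generator with per-stage ground truth.

The generator emulates the phenomena the correction stages target, each with
a known answer key:

* a skewed UMI pool (Dirichlet-distributed probabilities with extra mass on
  low-complexity homopolymer-run sequences, giving the heavy right tail of
  real UMI frequency distributions);
* per-read single-base UMI errors at a fixed rate, the substituted base
  carrying low call quality for most (but not all) error reads;
* cellular-barcode errors splitting part of a parent cell's reads onto a
  Hamming<=2 child barcode with the same gene-UMI pairs;
* empty-droplet background barcodes drawing molecules from the pooled
  expression profile, with small lognormal sizes;
* damaged cells with boosted mitochondrial load, extra intergenic reads and
  reduced reads per molecule, controlled by a continuous severity latent;
* optional two-species gene labels for merge audits.

Everything is driven by a single seed and returns both the observed
``Dataset`` and a ``GroundTruth`` answer key.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dropkit.records import Dataset
from dropkit.umi_distribution import UmiDistribution

_BASES = "ACGT"

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "sample_umi_pool",
    "simulate_dataset",
    "simulate_quality_features",
    "umi_correction_metrics",
    "merge_metrics",
    "count_rmse",
]


@dataclass
class SimulationConfig:
    """Generator settings; defaults describe a small saturated droplet run
    with 6-base UMIs and a 1% per-read UMI error rate."""

    n_cells: int = 24
    n_background: int = 480
    n_genes: int = 60
    gene_power: float = 1.0  # power-law exponent of expression magnitudes
    n_mito_genes: int = 4
    umi_length: int = 6
    cb_length: int = 8  # short-barcode regime: many near-identical CBs
    # UMI pool skew
    dirichlet_concentration: float = 2.0
    homopolymer_enrichment: float = 3.0
    # sizes
    cell_molecules_mean: float = 1000.0  # lognormal median
    cell_molecules_sigma: float = 0.35
    background_molecules_mean: float = 25.0
    background_molecules_sigma: float = 0.5
    reads_per_molecule_mean: float = 4.0  # geometric
    # errors
    umi_error_rate: float = 0.01  # per read
    error_quality: float = 12.0
    base_quality: float = 35.0
    quality_sd: float = 2.0
    high_quality_error_fraction: float = 0.4
    cb_error_cell_fraction: float = 0.3
    cb_split_fraction: float = 0.2  # molecules rerouted to the child CB
    cb_max_error_distance: int = 2
    # cell quality
    damaged_fraction: float = 0.15
    damaged_mito_boost: float = 0.5
    healthy_mito_fraction: float = 0.05
    healthy_intergenic_fraction: float = 0.05
    damaged_intergenic_boost: float = 0.3
    # species
    two_species: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "umi_error_rate",
            "cb_error_cell_fraction",
            "cb_split_fraction",
            "damaged_fraction",
            "high_quality_error_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class GroundTruth:
    """Answer key for one simulated dataset."""

    molecules: pd.DataFrame  # cb, gene, umi (one row per true molecule)
    umi_errors: pd.DataFrame  # cb, gene, umi, parent_umi, reads
    cb_errors: dict  # child CB -> parent CB
    cells: pd.DataFrame  # index cb: is_cell, damaged, severity, quality, species
    pool: UmiDistribution

    def true_counts(self) -> pd.Series:
        """True molecules per (cb, gene) including collided molecules."""
        return self.molecules.groupby(["cb", "gene"]).size()


def _all_umis(L: int) -> np.ndarray:
    return np.array(["".join(t) for t in itertools.product(_BASES, repeat=L)], dtype=object)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def sample_umi_pool(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> UmiDistribution:
    """Skewed UMI pool over all 4^L sequences.

    Dirichlet-distributed probabilities multiplied by a homopolymer boost
    ``1 + w (run - 1)`` (``run`` = longest single-base run), so higher
    enrichment weights concentrate mass on low-complexity sequences.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    seqs = _all_umis(cfg.umi_length)
    probs = rng.dirichlet(np.full(len(seqs), cfg.dirichlet_concentration))
    runs = np.array([_max_run(s) for s in seqs], dtype=float)
    probs = probs * (1.0 + cfg.homopolymer_enrichment * (runs - 1.0))
    probs = probs / probs.sum()
    return UmiDistribution(list(seqs), probs, cfg.umi_length)


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        cb = "".join(rng.choice(list(_BASES), size=length))
        out.add(cb)
    return sorted(out)


def _perturb_cb(cb: str, distance: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(cb), size=distance, replace=False)
    out = list(cb)
    for p in pos:
        out[p] = rng.choice([b for b in _BASES if b != out[p]])
    return "".join(out)


def simulate_dataset(cfg: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Generate one library; fully deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    pool = sample_umi_pool(cfg, rng)
    pool_seqs = np.array(pool.sequences, dtype=object)
    pool_probs = pool.probs

    genes = np.array(
        [
            (f"MT-g{i}" if i < cfg.n_mito_genes else f"g{i}")
            for i in range(cfg.n_genes)
        ],
        dtype=object,
    )
    if cfg.two_species:
        half = cfg.n_genes // 2
        genes = np.array(
            [f"hs_{g}" if i < half else f"mm_{g}" for i, g in enumerate(genes)],
            dtype=object,
        )
        species_of_gene = {g: ("human" if g.startswith("hs_") else "mouse") for g in genes}
    else:
        species_of_gene = {g: "single" for g in genes}
    mito_mask = np.array(["MT-" in g for g in genes])
    base_w = (np.arange(cfg.n_genes) + 1.0) ** (-cfg.gene_power)
    rng.shuffle(base_w)

    cbs = _random_barcodes(cfg.n_cells + cfg.n_background, cfg.cb_length, rng)
    rng.shuffle(cbs)
    cell_cbs = cbs[: cfg.n_cells]
    bg_cbs = cbs[cfg.n_cells :]

    n_damaged = int(round(cfg.damaged_fraction * cfg.n_cells))
    damaged = np.zeros(cfg.n_cells, dtype=bool)
    damaged[:n_damaged] = True
    rng.shuffle(damaged)
    severity = np.where(
        damaged, rng.uniform(0.5, 1.0, cfg.n_cells), rng.uniform(0.0, 0.2, cfg.n_cells)
    )
    if cfg.two_species:
        cell_species = rng.choice(["human", "mouse"], size=cfg.n_cells)
    else:
        cell_species = np.full(cfg.n_cells, "single", dtype=object)

    mol_cb, mol_gene, mol_umi = [], [], []
    inter_cb, inter_reads_list = [], []
    read_means = {}

    def gene_weights(species: str, sev: float) -> np.ndarray:
        # damage effects scale with sev^2: healthy cells (sev <= 0.2) stay at
        # the ambient baseline, damaged cells (sev >= 0.5) are clearly shifted
        w = base_w.copy()
        if cfg.two_species and species != "pooled":
            keep = np.array([species_of_gene[g] == species for g in genes])
            w = np.where(keep, w, 0.0)
        w = w / w.sum()
        mito_target = min(cfg.healthy_mito_fraction + cfg.damaged_mito_boost * sev**2, 0.9)
        cur = w[mito_mask].sum()
        if cur > 0:
            w[mito_mask] *= mito_target / cur
            w[~mito_mask] *= (1.0 - mito_target) / w[~mito_mask].sum()
        return w

    for i, cb in enumerate(cell_cbs):
        n_mol = max(20, int(rng.lognormal(np.log(cfg.cell_molecules_mean), cfg.cell_molecules_sigma)))
        w = gene_weights(cell_species[i], severity[i])
        g_idx = rng.choice(cfg.n_genes, size=n_mol, p=w)
        u_idx = rng.choice(len(pool_seqs), size=n_mol, p=pool_probs)
        mol_cb.extend([cb] * n_mol)
        mol_gene.extend(genes[g_idx])
        mol_umi.extend(pool_seqs[u_idx])
        read_means[cb] = cfg.reads_per_molecule_mean * (1.0 - 0.5 * severity[i] ** 2)
        inter_frac = (
            cfg.healthy_intergenic_fraction
            + cfg.damaged_intergenic_boost * severity[i] ** 2
        )
        inter_cb.append(cb)
        inter_reads_list.append(inter_frac)

    pooled_w = gene_weights("pooled", 0.1)
    for cb in bg_cbs:
        n_mol = max(
            1, int(rng.lognormal(np.log(cfg.background_molecules_mean), cfg.background_molecules_sigma))
        )
        g_idx = rng.choice(cfg.n_genes, size=n_mol, p=pooled_w)
        u_idx = rng.choice(len(pool_seqs), size=n_mol, p=pool_probs)
        mol_cb.extend([cb] * n_mol)
        mol_gene.extend(genes[g_idx])
        mol_umi.extend(pool_seqs[u_idx])
        read_means[cb] = max(cfg.reads_per_molecule_mean / 2.0, 1.5)
        # ambient material carries intergenic reads as well
        inter_cb.append(cb)
        inter_reads_list.append(cfg.healthy_intergenic_fraction)

    truth_molecules = pd.DataFrame({"cb": mol_cb, "gene": mol_gene, "umi": mol_umi})

    # collapse collisions: observed molecules are distinct (cb, gene, umi)
    obs = truth_molecules.groupby(["cb", "gene", "umi"], sort=True).size().reset_index(name="n_true")
    p_read = np.array([1.0 / read_means[cb] for cb in obs["cb"]])
    reads = rng.geometric(np.clip(p_read, 1e-6, 1.0))
    obs["reads"] = reads

    # per-read UMI errors (parent keeps at least one read)
    n_err_reads = rng.binomial(np.maximum(obs["reads"] - 1, 0), cfg.umi_error_rate)
    err_rows = []
    L = cfg.umi_length
    err_sources = np.flatnonzero(n_err_reads > 0)
    for i in err_sources:
        parent = obs["umi"].iat[i]
        variants: dict[str, int] = {}
        for _ in range(int(n_err_reads[i])):
            p = int(rng.integers(L))
            b = _BASES[int(rng.integers(4))]
            while b == parent[p]:
                b = _BASES[int(rng.integers(4))]
            v = parent[:p] + b + parent[p + 1 :]
            variants[v] = variants.get(v, 0) + 1
        for v, c in variants.items():
            err_rows.append(
                (obs["cb"].iat[i], obs["gene"].iat[i], v, parent, c)
            )
    obs["reads"] = obs["reads"] - n_err_reads
    umi_errors = pd.DataFrame(
        err_rows, columns=["cb", "gene", "umi", "parent_umi", "reads"]
    )

    # assemble records with qualities
    def qual_matrix(umis: list[str], n: int) -> np.ndarray:
        return rng.normal(cfg.base_quality, cfg.quality_sd, size=(n, L)).clip(2.0, 41.0)

    rec_cb = list(obs["cb"]) + list(umi_errors["cb"])
    rec_gene = list(obs["gene"]) + list(umi_errors["gene"])
    rec_umi = list(obs["umi"]) + list(umi_errors["umi"])
    rec_reads = list(obs["reads"]) + list(umi_errors["reads"])
    quals = qual_matrix(rec_umi, len(rec_cb))
    for j, (err_umi, parent) in enumerate(
        zip(umi_errors["umi"], umi_errors["parent_umi"])
    ):
        row = len(obs) + j
        pos = next(k for k in range(L) if err_umi[k] != parent[k])
        if rng.random() >= cfg.high_quality_error_fraction:
            quals[row, pos] = float(
                np.clip(rng.normal(cfg.error_quality, cfg.quality_sd), 2.0, 41.0)
            )
    inter_flags = [False] * len(rec_cb)

    # intergenic reads per cell, carried as flagged pseudo-gene records
    reads_by_cb = pd.Series(rec_reads, dtype=float).groupby(pd.Series(rec_cb)).sum()
    for cb, frac in zip(inter_cb, inter_reads_list):
        cell_reads = int(reads_by_cb.get(cb, 0))
        n_inter = int(round(frac * cell_reads / max(1e-9, 1.0 - frac)))
        if n_inter == 0:
            continue
        u_idx = rng.choice(len(pool_seqs), size=1, p=pool_probs)
        rec_cb.append(cb)
        rec_gene.append("__intergenic__")
        rec_umi.append(pool_seqs[u_idx[0]])
        rec_reads.append(n_inter)
        quals = np.vstack([quals, qual_matrix([pool_seqs[u_idx[0]]], 1)])
        inter_flags.append(True)

    # cellular-barcode splits
    cb_errors: dict[str, str] = {}
    n_split = int(round(cfg.cb_error_cell_fraction * cfg.n_cells))
    split_parents = sorted(rng.choice(cell_cbs, size=n_split, replace=False))
    existing = set(rec_cb)
    final_cb = list(rec_cb)
    add_cb, add_gene, add_umi, add_reads, add_quals, add_inter = [], [], [], [], [], []
    for parent in split_parents:
        d = int(rng.integers(1, cfg.cb_max_error_distance + 1))
        child = _perturb_cb(parent, d, rng)
        while child in existing or child in cb_errors:
            child = _perturb_cb(parent, d, rng)
        cb_errors[child] = parent
        rows = [
            i
            for i, c in enumerate(final_cb)
            if c == parent and not inter_flags[i] and rec_reads[i] >= 2
        ]
        chosen = [i for i in rows if rng.random() < cfg.cb_split_fraction]
        for i in chosen:
            moved = max(1, int(rec_reads[i]) // 2)
            rec_reads[i] = int(rec_reads[i]) - moved
            add_cb.append(child)
            add_gene.append(rec_gene[i])
            add_umi.append(rec_umi[i])
            add_reads.append(moved)
            add_quals.append(quals[i])
            add_inter.append(False)
    rec_cb = final_cb + add_cb
    rec_gene = list(rec_gene) + add_gene
    rec_umi = list(rec_umi) + add_umi
    rec_reads = list(rec_reads) + add_reads
    if add_quals:
        quals = np.vstack([quals, np.array(add_quals)])
    inter_flags = inter_flags + add_inter

    data = Dataset.from_arrays(
        rec_cb, rec_umi, rec_gene, rec_reads, quals, inter_flags, umi_length=L
    )

    cells = pd.DataFrame(
        {
            "is_cell": [True] * cfg.n_cells + [False] * cfg.n_background,
            "damaged": list(damaged) + [False] * cfg.n_background,
            "severity": list(severity) + [0.0] * cfg.n_background,
            "quality": list(1.0 - severity) + [0.0] * cfg.n_background,
            "species": list(cell_species) + ["background"] * cfg.n_background,
        },
        index=cell_cbs + bg_cbs,
    )
    truth = GroundTruth(truth_molecules, umi_errors, cb_errors, cells, pool)
    return data, truth


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------


def _keys(data: Dataset) -> set[tuple]:
    df = data.df.loc[~data.df["intergenic"]]
    return set(zip(df["cb"], df["gene"], df["umi"]))


def umi_correction_metrics(
    original: Dataset, corrected: Dataset, truth: GroundTruth
) -> dict:
    """Precision / recall / F1 of erroneous-molecule removal.

    Injected error molecules that coincide with a true molecule of the same
    gene and cell are excluded from the positives (removing them would
    delete a real molecule)."""
    true_keys = set(zip(truth.molecules["cb"], truth.molecules["gene"], truth.molecules["umi"]))
    err_keys = {
        k
        for k in zip(truth.umi_errors["cb"], truth.umi_errors["gene"], truth.umi_errors["umi"])
        if k not in true_keys
    }
    present = _keys(original)
    removed = present - _keys(corrected)
    err_present = err_keys & present
    tp = len(removed & err_present)
    fp = len(removed - err_present)
    fn = len(err_present - removed)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def merge_metrics(plan_targets: dict, truth: GroundTruth) -> dict:
    """Recovery of injected CB splits: fraction of children merged back to
    their true parent, plus false merges of real (non-child) barcodes."""
    children = set(truth.cb_errors)
    merged = {s: t for s, t in plan_targets.items() if t is not None}
    recovered = sum(
        1 for c, p in truth.cb_errors.items() if merged.get(c) == p
    )
    false_sources = [s for s in merged if s not in children]
    return {
        "n_children": len(children),
        "recovered": recovered,
        "recovery_rate": recovered / len(children) if children else 1.0,
        "false_merges": len(false_sources),
    }


def evaluate_against_truth(
    original: Dataset,
    corrected: Dataset,
    truth: GroundTruth,
    plan_targets: dict | None = None,
) -> dict:
    """Combined per-stage metrics against the answer key."""
    out = {"umi": umi_correction_metrics(original, corrected, truth)}
    out["rmse"] = count_rmse(corrected, truth)
    if plan_targets is not None:
        out["merge"] = merge_metrics(plan_targets, truth)
    return out


def count_rmse(corrected: Dataset, truth: GroundTruth) -> float:
    """RMSE of per-(cb, gene) molecule counts against the true table."""
    est = corrected.df.loc[~corrected.df["intergenic"]].groupby(["cb", "gene"]).size()
    true = truth.true_counts()
    joined = pd.concat([est, true], axis=1, keys=["est", "true"]).fillna(0.0)
    return float(np.sqrt(np.mean((joined["est"] - joined["true"]) ** 2)))


# ---------------------------------------------------------------------------
# classifier feature generator
# ---------------------------------------------------------------------------


def simulate_quality_features(
    n_per_class: int = 250,
    label_noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Two-population technical feature table for classifier benchmarks.

    High-quality cells: low mitochondrial and intergenic fractions, high
    reads per UMI, large sizes.  Low-quality cells: the damaged profile and
    small sizes.  Returns ``(features, noisy_labels, true_labels, sizes)``
    where ``label_noise`` is the symmetric label-flip probability applied
    to the training labels.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    cls = np.array(["high"] * n_per_class + ["low"] * n_per_class, dtype=object)
    hi = rng.normal(
        [0.05, 4.0, 1.6, 0.55, 0.05], [0.02, 0.7, 0.25, 0.06, 0.02], size=(n_per_class, 5)
    )
    lo = rng.normal(
        [0.35, 1.8, 1.15, 0.8, 0.25], [0.08, 0.45, 0.12, 0.06, 0.07], size=(n_per_class, 5)
    )
    X = np.vstack([hi, lo])
    X[:, [0, 3, 4]] = X[:, [0, 3, 4]].clip(0.0, 1.0)
    X[:, 1] = X[:, 1].clip(1.0, None)
    X[:, 2] = X[:, 2].clip(1.0, None)
    idx = [f"cell{i:04d}" for i in range(n)]
    features = pd.DataFrame(
        X,
        index=idx,
        columns=[
            "mito_fraction",
            "reads_per_umi",
            "umis_per_gene",
            "low_exp_fraction",
            "intergenic_fraction",
        ],
    )
    true_labels = pd.Series(cls, index=idx)
    noisy = true_labels.copy()
    flip = rng.random(n) < label_noise
    noisy[flip] = np.where(noisy[flip] == "high", "low", "high")
    sizes = pd.Series(
        np.concatenate(
            [
                rng.lognormal(np.log(1200), 0.4, n_per_class),
                rng.lognormal(np.log(90), 0.5, n_per_class),
            ]
        ),
        index=idx,
    )
    return features, noisy, true_labels, sizes


def benchmark_quality_classifier(
    n_per_class: int = 250,
    label_noise: float = 0.10,
    seed: int = 0,
    n_folds: int = 5,
) -> dict:
    """Cross-validation and robustness protocol for the KDE cell classifier.

    Returns fold-mean sensitivity and specificity (training on noisy labels,
    scoring against the true ones), class-1 (high) assignment agreement
    after removing a random 20% of the training data, and the minimum
    agreement when the size thresholds that seed the initial labels are
    widened / narrowed by 20%.
    """
    from dropkit.cell_quality import (
        SizeThresholds,
        initial_labels,
        score_cells,
        size_thresholds,
        train_quality_classifier,
    )

    features, noisy, true_labels, sizes = simulate_quality_features(
        n_per_class, label_noise, seed
    )
    rng = np.random.default_rng(seed + 1)
    idx = np.array(features.index)
    rng.shuffle(idx)
    folds = np.array_split(idx, n_folds)
    sens, spec = [], []
    for k in range(n_folds):
        test = pd.Index(folds[k])
        train = features.index.difference(test)
        clf = train_quality_classifier(features.loc[train], noisy.loc[train])
        pred = score_cells(clf, features.loc[test]) >= 0.5
        t = (true_labels.loc[test] == "high").to_numpy()
        sens.append(float(np.mean(pred.to_numpy()[t])))
        spec.append(float(np.mean(~pred.to_numpy()[~t])))

    clf_full = train_quality_classifier(features, noisy)
    base_high = (score_cells(clf_full, features) >= 0.5).to_numpy()

    keep = pd.Index(rng.choice(idx, size=int(0.8 * len(idx)), replace=False))
    clf_sub = train_quality_classifier(features.loc[keep], noisy.loc[keep])
    sub_high = (score_cells(clf_sub, features) >= 0.5).to_numpy()
    stab_removal = float(np.mean(sub_high[base_high] == True))  # noqa: E712

    th = size_thresholds(sizes.to_numpy())
    base_labels = initial_labels(sizes, th)
    clf_base = train_quality_classifier(features, base_labels)
    ref_high = (score_cells(clf_base, features) >= 0.5).to_numpy()
    agreements = []
    for t_l, t_u in ((0.8 * th.t_l, 1.2 * th.t_u), (1.2 * th.t_l, 0.8 * th.t_u)):
        labels = initial_labels(sizes, SizeThresholds(min(t_l, t_u), max(t_l, t_u)))
        clf_p = train_quality_classifier(features, labels)
        p_high = (score_cells(clf_p, features) >= 0.5).to_numpy()
        agreements.append(float(np.mean(p_high[ref_high] == True)))  # noqa: E712
    return {
        "cv_sensitivity": float(np.mean(sens)),
        "cv_specificity": float(np.mean(spec)),
        "stability_removal": stab_removal,
        "stability_thresholds": float(min(agreements)),
    }
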