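"""Damaged / low-quality cell classification.

Cell sizes (molecules per barcode) alone separate obvious cells from obvious
background, but intermediate-size barcodes mix real cells with damaged ones.
The approach here: (1) locate the linear region of the log-size vs log-rank
curve to obtain size thresholds ``t_L`` / ``t_U``; (2) label cells below
``t_L`` low-quality and the top 75% above ``t_U`` high-quality, leaving the
rest unknown; (3) build technical per-cell features (mitochondrial UMI
fraction, mean reads per UMI, mean UMIs per gene, fraction of one-molecule
genes, intergenic read fraction); (4) reduce to three sparse principal
components fitted on robustly standardized features and classify with
class-conditional kernel density estimates (normal-scale bandwidth), which
tolerates the label noise inherent in the size-based initial labels.
Extreme mitochondrial / intergenic fractions are handled before or after
training depending on whether those features load on the retained
components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from sklearn.decomposition import SparsePCA

from dropkit.records import Dataset

logger = logging.getLogger("dropkit")

__all__ = [
    "SizeThresholds",
    "size_thresholds",
    "initial_labels",
    "extract_features",
    "extreme_fraction_threshold",
    "QualityClassifier",
    "train_quality_classifier",
    "score_cells",
    "filter_cells",
]

FRACTION_FEATURES = ("mito_fraction", "intergenic_fraction")


@dataclass
class SizeThresholds:
    """Borders of the linear region of the barcode-rank curve (in molecule
    counts); cells above ``t_u`` are confidently real, below ``t_l``
    confidently background."""

    t_l: float
    t_u: float

    def __post_init__(self) -> None:
        if self.t_l > self.t_u:
            raise ValueError("t_l must not exceed t_u")


def size_thresholds(sizes: np.ndarray, smooth: float | None = None) -> SizeThresholds:
    """Detect the linear part of the log(size) vs log(rank) curve.

    A smoothing spline estimates the curvature of the curve; ``t_u`` is the
    size where curvature first enters a near-zero band (10% of the maximum
    absolute curvature) and ``t_l`` the size at the last rank before the
    curvature turns decisively positive.  Degenerate curves without the
    concave-linear-convex structure raise, pointing at manual thresholds.
    """
    sizes = np.sort(np.asarray(sizes, dtype=float))[::-1]
    if len(sizes) < 100:
        raise ValueError("need at least 100 barcodes to locate thresholds")
    ranks = np.arange(1, len(sizes) + 1)
    x = np.log(ranks)
    y = np.log(np.maximum(sizes, 0.5))
    # smoothing allows ~0.05 residual in log-size per point, enough to wash
    # out sampling noise while keeping the knee structure
    if smooth is None:
        smooth = len(x) * 0.0025
    spl = UnivariateSpline(x, y, k=4, s=smooth)
    xx = np.linspace(x[0], x[-1], 400)
    curv = spl.derivative(2)(xx)
    if np.max(np.abs(curv)) < 0.1:  # log-log curve without meaningful bend
        raise ValueError("no knee in rank curve: specify thresholds manually")
    band = 0.10 * np.max(np.abs(curv))
    negative = np.flatnonzero(curv < -band)
    if len(negative) == 0:
        raise ValueError("no concave region in rank curve: specify thresholds manually")
    # the linear part starts where curvature returns to the near-zero band
    # after the concave region, and ends just before it turns convex
    after_concave = np.flatnonzero((np.abs(curv) <= band) & (np.arange(len(xx)) > negative[0]))
    if len(after_concave) == 0:
        raise ValueError("no linear region in rank curve: specify thresholds manually")
    first_in = int(after_concave[0])
    positive = np.flatnonzero((curv > band) & (np.arange(len(xx)) > first_in))
    if len(positive) == 0:
        raise ValueError("no convex tail in rank curve: specify thresholds manually")
    last_before_pos = int(positive[0]) - 1
    rank_u = int(np.clip(np.round(np.exp(xx[first_in])), 1, len(sizes)))
    rank_l = int(np.clip(np.round(np.exp(xx[last_before_pos])), 1, len(sizes)))
    t_u = float(sizes[rank_u - 1])
    t_l = float(sizes[rank_l - 1])
    if t_l > t_u:
        t_l, t_u = t_u, t_l
    return SizeThresholds(t_l, t_u)


def initial_labels(sizes: pd.Series, th: SizeThresholds) -> pd.Series:
    """Size-based training labels.

    ``low``: size < t_L.  ``high``: the largest 75% among cells above t_U
    (size-ranked, so the assignment is deterministic).  Everything else,
    including the bottom quarter above t_U, is ``unknown``.
    """
    labels = pd.Series("unknown", index=sizes.index, dtype=object)
    labels[sizes < th.t_l] = "low"
    above = sizes[sizes > th.t_u].sort_values(ascending=False, kind="stable")
    n_high = int(np.floor(0.75 * len(above)))
    labels[above.index[:n_high]] = "high"
    return labels


def extract_features(data: Dataset, mito_genes: set[str] | None = None) -> pd.DataFrame:
    """Per-cell technical feature table.

    Index: cellular barcode.  Columns: ``mito_fraction`` (mitochondrial
    UMIs / total UMIs), ``reads_per_umi`` (mean), ``umis_per_gene`` (mean),
    ``low_exp_fraction`` (genes with exactly one molecule), and
    ``intergenic_fraction`` (of reads).
    """
    if not mito_genes:
        if mito_genes is not None and len(mito_genes) == 0:
            warnings.warn("empty mitochondrial gene list: mito fractions set to 0")
        mito_genes = set()
    df = data.df
    genic = df.loc[~df["intergenic"]]
    mol = genic.groupby("cb").size()
    reads = genic.groupby("cb")["reads"].sum()
    mito = genic.loc[genic["gene"].isin(mito_genes)].groupby("cb").size()
    per_gene = genic.groupby(["cb", "gene"]).size()
    umis_per_gene = per_gene.groupby("cb").mean()
    low_exp = (per_gene == 1).groupby("cb").mean()
    inter_reads = df.loc[df["intergenic"]].groupby("cb")["reads"].sum()
    total_reads = df.groupby("cb")["reads"].sum()
    out = pd.DataFrame(index=mol.index)
    out["mito_fraction"] = mito.reindex(mol.index).fillna(0) / mol
    out["reads_per_umi"] = reads / mol
    out["umis_per_gene"] = umis_per_gene
    out["low_exp_fraction"] = low_exp
    out["intergenic_fraction"] = (
        inter_reads.reindex(mol.index).fillna(0) / total_reads.reindex(mol.index)
    )
    return out.sort_index()


def extreme_fraction_threshold(values: np.ndarray) -> float:
    """Outlier threshold for a fraction feature: 20% trimmed mean plus four
    median absolute deviations."""
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 values")
    m = stats.trim_mean(values, 0.2)
    a = stats.median_abs_deviation(values, scale=1.0)
    return float(m + 4 * a)


def _robust_standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = np.median(X, axis=0)
    scale = stats.median_abs_deviation(X, axis=0, scale="normal")
    scale = np.where(scale <= 0, np.std(X, axis=0) + 1e-12, scale)
    return (X - center) / scale, center, scale


def _normal_scale_bandwidth(X: np.ndarray) -> np.ndarray:
    """Normal-reference bandwidth (diagonal) for a d-dim KDE."""
    n, d = X.shape
    factor = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))
    return factor * np.std(X, axis=0, ddof=1)


class _DiagKDE:
    def __init__(self, X: np.ndarray):
        self.X = X
        self.h = np.maximum(_normal_scale_bandwidth(X), 1e-9)

    def __call__(self, Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(Y)
        z = (Y[:, None, :] - self.X[None, :, :]) / self.h
        log_k = -0.5 * np.sum(z**2, axis=2)
        norm = np.prod(self.h) * (2 * np.pi) ** (self.X.shape[1] / 2)
        return np.exp(log_k).sum(axis=1) / (len(self.X) * norm)


@dataclass
class QualityClassifier:
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (3, n_features) sparse loadings
    kde_high: _DiagKDE
    kde_low: _DiagKDE
    prior_high: float
    prelabel: dict  # fraction feature -> bool (labeled before training)
    extreme: dict  # fraction feature -> threshold

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        return ((X - self.center) / self.scale) @ self.components.T


def train_quality_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    sparsity: float = 1.0,
    prior_high: float = 0.5,
    random_state: int = 0,
) -> QualityClassifier:
    """Fit the three-component sparse-PCA + KDE classifier.

    Extreme-fraction handling: when the mitochondrial or intergenic fraction
    loads at >= 5% of a retained component's total loading magnitude, cells
    with extreme values of that fraction are relabeled low *before* the
    final fit; otherwise they are forced to score 0 after scoring.
    """
    feature_names = [c for c in features.columns if features[c].notna().all()]
    labels = labels.reindex(features.index).fillna("unknown")
    extreme = {
        f: extreme_fraction_threshold(features[f].to_numpy())
        for f in FRACTION_FEATURES
        if f in feature_names
    }

    def fit(labs: pd.Series):
        train_idx = labs.index[labs.isin(["high", "low"])]
        if (labs[train_idx] == "high").sum() < 20 or (labs[train_idx] == "low").sum() < 20:
            raise ValueError("both classes need at least 20 labeled cells")
        X = features.loc[train_idx, feature_names].to_numpy(dtype=float)
        Xs, center, scale = _robust_standardize(X)
        spca = SparsePCA(
            n_components=3, alpha=sparsity, ridge_alpha=0.01, random_state=random_state
        )
        scores = spca.fit_transform(Xs)
        return train_idx, center, scale, spca.components_, scores

    train_idx, center, scale, components, scores = fit(labels)
    prelabel = {}
    for f in extreme:
        j = feature_names.index(f)
        loading_frac = np.abs(components[:, j]) / np.maximum(
            np.abs(components).sum(axis=1), 1e-12
        )
        prelabel[f] = bool((loading_frac >= 0.05).any())
    relabeled = labels.copy()
    changed = False
    for f, pre in prelabel.items():
        if pre:
            mask = features[f] > extreme[f]
            relabeled[features.index[mask]] = "low"
            changed = True
    if changed:
        train_idx, center, scale, components, scores = fit(relabeled)
        labels = relabeled
    is_high = (labels[train_idx] == "high").to_numpy()
    kde_high = _DiagKDE(scores[is_high])
    kde_low = _DiagKDE(scores[~is_high])
    return QualityClassifier(
        feature_names,
        center,
        scale,
        components,
        kde_high,
        kde_low,
        prior_high,
        prelabel,
        extreme,
    )


def score_cells(clf: QualityClassifier, features: pd.DataFrame) -> pd.Series:
    """Posterior probability of the high-quality class per cell.

    Fraction features handled post hoc (not pre-labeled) force extreme
    cells to score 0.
    """
    Z = clf.transform(features)
    f_hi = clf.kde_high(Z) * clf.prior_high
    f_lo = clf.kde_low(Z) * (1.0 - clf.prior_high)
    total = f_hi + f_lo
    score = np.where(total > 0, f_hi / np.maximum(total, 1e-300), 0.5)
    score = pd.Series(score, index=features.index, name="quality_score")
    for f, pre in clf.prelabel.items():
        if not pre and f in features.columns:
            score[features[f] > clf.extreme[f]] = 0.0
    return score.clip(0.0, 1.0)


def filter_cells(
    scores: pd.Series,
    sizes: pd.Series,
    th: SizeThresholds,
    genes_per_cell: pd.Series | None = None,
    keep_hi: float = 0.9,
    drop_lo: float = 0.1,
    min_genes: int = 0,
) -> pd.DataFrame:
    """Final keep / rescue / filter decision per cell.

    Cells above the upper size threshold are kept unless their score falls
    below ``drop_lo``; cells below it are rescued when the score exceeds
    ``keep_hi``.  A minimum expressed-gene count applies throughout.
    """
    idx = scores.index
    sizes = sizes.reindex(idx).fillna(0)
    genes = (
        genes_per_cell.reindex(idx).fillna(0)
        if genes_per_cell is not None
        else pd.Series(np.inf, index=idx)
    )
    big = sizes >= th.t_u
    keep = (big & (scores >= drop_lo)) | (~big & (scores > keep_hi))
    keep &= genes >= min_genes
    status = np.where(
        keep & ~big, "rescued", np.where(keep, "kept", np.where(big, "filtered", "background"))
    )
    return pd.DataFrame({"size": sizes, "score": scores, "kept": keep, "status": status})
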