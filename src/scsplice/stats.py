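"""Evaluation statistics for splicing observations.

* binary / bimodality metrics of observed PSI matrices;
* Kruskal–Wallis differential splicing across cell clusters;
* fold-enrichment evaluation of a filter's selected exon set against the
  low-p-value exons (hypergeometric test, Benjamini–Hochberg correction,
  confusion-matrix scores);
* a Geary's C-style autocorrelation permutation test asking whether an
  exon's PSI is smooth over the cell embedding;
* a plain PCA embedding utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from ._rng import stage_rng

__all__ = [
    "BimodalityReport",
    "EnrichmentResult",
    "AutocorrResult",
    "binary_metrics",
    "bimodality_flag",
    "kruskal_wallis_by_cluster",
    "evaluate_filter_enrichment",
    "autocorrelation_test",
    "compute_embedding",
]


@dataclass
class BimodalityReport:
    """Binary-observation summaries of a PSI matrix (NaN-aware)."""

    exon_binary_proportion: pd.Series
    cell_binary_proportion: pd.Series
    exon_bimodal: pd.Series
    exon_intermediate: pd.Series  # mean PSI inside the intermediate window
    exon_mean_psi: pd.Series


def _binary_mask(values: np.ndarray) -> np.ndarray:
    return (values == 0.0) | (values == 1.0)


def binary_metrics(
    psi: pd.DataFrame,
    intermediate_window: tuple[float, float] = (0.2, 0.8),
    bimodal_low: float = 0.25,
    bimodal_high: float = 0.75,
    bimodal_tail_fraction: float = 0.25,
) -> BimodalityReport:
    """Per-exon and per-cell proportions of binary observations.

    An observation is binary when the observed PSI is exactly 0 or 1 (only
    one isoform seen).  Missing observations count in neither numerator nor
    denominator; exons (or cells) with no observations get NaN.
    """
    v = psi.to_numpy(dtype=float)
    obs = np.isfinite(v)
    binary = _binary_mask(v) & obs
    with np.errstate(invalid="ignore"):
        exon_prop = binary.sum(0) / obs.sum(0)
        cell_prop = binary.sum(1) / obs.sum(1)
        mean_psi = np.where(obs, v, 0.0).sum(0) / obs.sum(0)
    lo, hi = intermediate_window
    exon_prop = pd.Series(exon_prop, index=psi.columns)
    mean_psi = pd.Series(mean_psi, index=psi.columns)
    bimodal = pd.Series(
        [
            (
                bimodality_flag(psi[c], bimodal_low, bimodal_high, bimodal_tail_fraction)
                if np.isfinite(psi[c]).any()
                else None
            )
            for c in psi.columns
        ],
        index=psi.columns,
        dtype=object,
    )
    return BimodalityReport(
        exon_binary_proportion=exon_prop,
        cell_binary_proportion=pd.Series(cell_prop, index=psi.index),
        exon_bimodal=bimodal,
        exon_intermediate=(mean_psi > lo) & (mean_psi < hi),
        exon_mean_psi=mean_psi,
    )


def bimodality_flag(
    psi_column: pd.Series | np.ndarray,
    low: float = 0.25,
    high: float = 0.75,
    tail_fraction: float = 0.25,
) -> bool:
    """Heuristic bimodality call: at least ``tail_fraction`` of the exon's
    observations at PSI <= low AND at least that fraction at PSI >= high."""
    v = np.asarray(psi_column, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("bimodality flag needs at least one observation")
    return bool(np.mean(v <= low) >= tail_fraction and np.mean(v >= high) >= tail_fraction)


def kruskal_wallis_by_cluster(
    psi: pd.DataFrame,
    cluster_labels: pd.Series,
    min_obs_per_cluster: int = 2,
    min_clusters: int = 2,
) -> pd.Series:
    """Per-exon Kruskal–Wallis p-value of PSI differences across clusters.

    Clusters contributing fewer than ``min_obs_per_cluster`` non-missing
    observations are dropped from that exon's test; exons left with fewer
    than ``min_clusters`` clusters get NaN.  All-tied data is defined as
    p = 1 (no evidence of any shift).
    """
    labels = cluster_labels.reindex(psi.index)
    pvals = {}
    groups_index = {g: np.asarray(idx) for g, idx in labels.groupby(labels).groups.items()}
    for exon in psi.columns:
        col = psi[exon]
        samples = []
        for g, idx in groups_index.items():
            v = col.loc[idx].dropna().to_numpy()
            if v.size >= min_obs_per_cluster:
                samples.append(v)
        if len(samples) < min_clusters:
            pvals[exon] = np.nan
            continue
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            pvals[exon] = 1.0
            continue
        pvals[exon] = sps.kruskal(*samples).pvalue
    return pd.Series(pvals, name="kw_pvalue")


@dataclass
class EnrichmentResult:
    """Enrichment of a selected exon set for low-p-value exons at one threshold."""

    p_threshold: float
    universe_size: int  # |M|
    significant: int  # |m|
    selected: int  # |P|
    selected_significant: int  # |p|
    fold: float
    pvalue: float  # upper-tail hypergeometric
    qvalue: float  # BH-adjusted across the threshold grid
    precision: float
    recall: float
    specificity: float
    accuracy: float
    f1: float


DEFAULT_THRESHOLD_GRID = (0.1, 0.05, 0.01, 1e-3, 1e-4, 1e-5)


def evaluate_filter_enrichment(
    universe_pvalues: pd.Series,
    selected: set | pd.Index,
    p_threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
) -> list[EnrichmentResult]:
    """Fold enrichment of ``selected`` for low-p exons over a threshold grid.

    fold = (|M| * |p|) / (|P| * |m|), with M the tested universe, m the
    exons at p <= x, P the selected subset, and p their intersection.
    Significance is the upper-tail hypergeometric probability of drawing at
    least |p| significant exons in |P| draws; BH correction is applied
    across the grid.  Confusion-matrix scores treat p as true positives.
    """
    pv = universe_pvalues.dropna()
    universe = set(pv.index)
    selected = set(selected) & universe
    big_m = len(universe)
    big_p = len(selected)
    results = []
    raw_pvals = []
    for x in p_threshold_grid:
        sig = set(pv.index[pv <= x])
        small_m = len(sig)
        small_p = len(sig & selected)
        if small_m == 0 or big_p == 0:
            fold = np.nan
            hyper_p = np.nan
        else:
            fold = (big_m * small_p) / (big_p * small_m)
            hyper_p = float(sps.hypergeom.sf(small_p - 1, big_m, small_m, big_p))
        tp = small_p
        fp = big_p - small_p
        fn = small_m - small_p
        tn = big_m - small_m - fp
        precision = tp / big_p if big_p else np.nan
        recall = tp / small_m if small_m else np.nan
        specificity = tn / (tn + fp) if (tn + fp) else np.nan
        accuracy = (tp + tn) / big_m if big_m else np.nan
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
        raw_pvals.append(hyper_p)
        results.append(
            EnrichmentResult(
                p_threshold=x,
                universe_size=big_m,
                significant=small_m,
                selected=big_p,
                selected_significant=small_p,
                fold=fold,
                pvalue=hyper_p,
                qvalue=np.nan,
                precision=precision,
                recall=recall,
                specificity=specificity,
                accuracy=accuracy,
                f1=f1,
            )
        )
    finite = np.isfinite(raw_pvals)
    if finite.any():
        q = np.full(len(raw_pvals), np.nan)
        q[finite] = multipletests(np.asarray(raw_pvals)[finite], method="fdr_bh")[1]
        for res, qv in zip(results, q):
            res.qvalue = float(qv) if np.isfinite(qv) else np.nan
    return results


# ---------------------------------------------------------------------------
# Geary's C-style autocorrelation permutation test


@dataclass
class AutocorrResult:
    exon_id: str
    score: float  # C'
    pvalue: float  # (x + 1) / (n_perm + 1), NaN when undefined
    mean_psi: float
    missing_fraction: float
    bin_id: tuple[int, int]  # (psi bin, missingness bin)


#: Folded mean-PSI bins: symmetric around 0.5, matching the binning used to
#: build the permutation null (values outside [0.05, 0.95] fold into bin 0).
PSI_BIN_EDGES = ((0.05, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4), (0.4, 0.6))
MISSING_BIN_EDGES = (0.0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def _psi_bin(mean_psi: float) -> int:
    folded = min(mean_psi, 1.0 - mean_psi)
    for i, (lo, hi) in enumerate(PSI_BIN_EDGES):
        if lo <= folded < hi or (i == len(PSI_BIN_EDGES) - 1 and folded >= lo):
            return i
    return 0  # outside [0.05, 0.95]: nearest (most extreme) bin


def _missing_bin(frac: float) -> int:
    idx = int(np.searchsorted(MISSING_BIN_EDGES, frac, side="right")) - 1
    return int(np.clip(idx, 0, len(MISSING_BIN_EDGES) - 2))


def _geary_score(values: np.ndarray, weights: np.ndarray) -> float:
    """C' for one exon's normalized values over the embedding neighbor graph.

    NaN cells are dropped from every sum; pairs with a missing member
    contribute nothing and the weight total W is restricted accordingly.
    Returns NaN when fewer than 3 cells are observed or variance is zero.
    """
    obs = np.isfinite(values)
    n = int(obs.sum())
    if n < 3:
        return np.nan
    v = values[obs]
    if np.all(v == v[0]):
        return np.nan
    w = weights[np.ix_(obs, obs)]
    w_total = w.sum()
    denom = np.sum((v - v.mean()) ** 2)
    if denom == 0 or w_total == 0:
        return np.nan
    diff2 = (v[:, None] - v[None, :]) ** 2
    num = float((w * diff2).sum())
    return 1.0 - (n - 1) * num / (2.0 * w_total * denom)


def _knn_weights(embedding: np.ndarray, k: int) -> np.ndarray:
    """Gaussian nearest-neighbor weights w_jk = exp(-d_jk^2 / sigma_j^2).

    sigma_j is the distance from cell j to its K-th nearest neighbor;
    non-neighbors (and the cell itself) get weight 0.
    """
    n = embedding.shape[0]
    k = int(min(max(k, 1), n - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    # first column is the cell itself (distance 0)
    dist, idx = dist[:, 1:], idx[:, 1:]
    sigma = dist[:, -1]
    sigma[sigma == 0] = np.finfo(float).eps
    w = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    w[rows, idx.ravel()] = np.exp(-(dist.ravel() ** 2) / (sigma[rows] ** 2))
    return w


def normalize_psi_per_cell(psi: pd.DataFrame, normalize_by: str = "variance") -> pd.DataFrame:
    """Center each cell's PSI values and divide by the per-cell variance
    (the printed normalization; ``normalize_by="sd"`` divides by the standard
    deviation instead — the choice cancels inside C' and only rescales)."""
    v = psi.to_numpy(dtype=float)
    mean_j = np.nanmean(v, axis=1, keepdims=True)
    var_j = np.nanvar(v, axis=1, keepdims=True)
    scale = var_j if normalize_by == "variance" else np.sqrt(var_j)
    scale = np.where(scale == 0, np.nan, scale)
    return pd.DataFrame((v - mean_j) / scale, index=psi.index, columns=psi.columns)


def autocorrelation_test(
    psi: pd.DataFrame,
    embedding: np.ndarray,
    k_neighbors: int | None = None,
    n_perm: int = 20_000,
    rng_seed: int = 0,
    normalize_by: str = "variance",
) -> list[AutocorrResult]:
    """Permutation test for embedding-smooth PSI per exon.

    Cells' PSI values are normalized per cell across all tested exons, then
    each exon is scored with a Geary's C variant over Gaussian K-nearest-
    neighbor weights (K defaults to half the number of cells).  The null is
    built by shuffling exon columns across cells; to respect the strong
    dependence of C' on an exon's mean PSI and missingness, exons are binned
    by folded mean PSI and missing fraction, ``n_perm`` shuffled exons are
    scored per bin (cycling over the bin's members), and each exon's
    p-value is (x + 1) / (n_perm + 1) with x the number of shuffled scores
    in its bin strictly above its own.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] != psi.shape[0]:
        raise ValueError("embedding rows must match PSI matrix rows (cells)")
    n_cells = psi.shape[0]
    if k_neighbors is None:
        k_neighbors = n_cells // 2
    weights = _knn_weights(embedding, k_neighbors)
    norm = normalize_psi_per_cell(psi, normalize_by).to_numpy(dtype=float)

    v_raw = psi.to_numpy(dtype=float)
    mean_psi = np.nanmean(v_raw, axis=0)
    missing_frac = np.mean(~np.isfinite(v_raw), axis=0)

    bins: dict[tuple[int, int], list[int]] = {}
    for j, exon in enumerate(psi.columns):
        if not np.isfinite(mean_psi[j]):
            continue
        key = (_psi_bin(float(mean_psi[j])), _missing_bin(float(missing_frac[j])))
        bins.setdefault(key, []).append(j)

    scores = np.array([_geary_score(norm[:, j], weights) for j in range(psi.shape[1])])

    rng = stage_rng(rng_seed, "permutation")
    null_scores: dict[tuple[int, int], np.ndarray] = {}
    for key, members in bins.items():
        pool = np.empty(n_perm)
        pool.fill(np.nan)
        for i in range(n_perm):
            j = members[i % len(members)]
            pool[i] = _geary_score(rng.permutation(norm[:, j]), weights)
        null_scores[key] = pool

    results = []
    for j, exon in enumerate(psi.columns):
        if not np.isfinite(mean_psi[j]):
            results.append(AutocorrResult(exon, np.nan, np.nan, np.nan, 1.0, (-1, -1)))
            continue
        key = (_psi_bin(float(mean_psi[j])), _missing_bin(float(missing_frac[j])))
        score = scores[j]
        if not np.isfinite(score):
            pval = np.nan
        else:
            pool = null_scores[key]
            x = int(np.sum(pool[np.isfinite(pool)] > score))
            pval = (x + 1) / (n_perm + 1)
        results.append(
            AutocorrResult(
                exon_id=str(exon),
                score=float(score),
                pvalue=float(pval) if np.isfinite(pval) else np.nan,
                mean_psi=float(mean_psi[j]),
                missing_fraction=float(missing_frac[j]),
                bin_id=key,
            )
        )
    return results


def compute_embedding(expression: pd.DataFrame | np.ndarray, n_components: int = 2) -> np.ndarray:
    """PCA scores of log1p, per-cell depth-normalized expression counts."""
    x = np.asarray(expression, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    depth = x.sum(axis=1, keepdims=True)
    if np.all(x == x.flat[0]):
        raise ValueError("constant expression matrix has no principal axes")
    depth[depth == 0] = 1.0
    norm = np.log1p(x / depth * 1e4)
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(norm)
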