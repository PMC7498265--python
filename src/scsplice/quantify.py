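"""mRNA-recovery-aware quantification of splicing observations.

Pipeline for junction-count data (real or simulated):

* ``estimate_psi_from_junctions`` — observed PSI per cell and exon from
  inclusion (SJA) and exclusion (SJB) junction reads, with the
  two-junctions-per-inclusion-molecule correction
  psi_hat = SJA / (SJA + 2 SJB).
* ``census_counts`` — a Census-style conversion of relative TPM to captured
  mRNA counts per cell, via the mode of the log-TPM distribution.
* ``coverage_rate`` — per-cell expected reads per splice junction per
  captured molecule, calibrated on constitutive junctions.
* ``filter_observations`` — keep observations backed by at least
  ``min_mrna`` captured molecules of the gene AND at least the junction
  reads expected from ``min_mrna`` informative molecules.
* ``baseline_filter`` — the flat >= 10-reads-in->= 50%-of-cells benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PsiEstimate",
    "CensusEstimate",
    "estimate_psi_from_junctions",
    "census_counts",
    "coverage_rate",
    "filter_observations",
    "cluster_retention",
    "baseline_filter",
]

JUNCTION_COLUMNS = ("cell_id", "exon_id", "SJA", "SJB")


@dataclass
class PsiEstimate:
    """Observed PSI and junction coverage, cells x exons (NaN = no reads)."""

    psi: pd.DataFrame
    coverage: pd.DataFrame  # SJ = SJA + SJB


def estimate_psi_from_junctions(
    junction_table: pd.DataFrame,
    weighting: Literal["halved_exclusion", "simulated"] = "halved_exclusion",
) -> PsiEstimate:
    """Observed PSI from a long junction-count table.

    The default weighting divides by SJA + 2*SJB: an mRNA that includes the
    exon exposes two informative junctions while a skipping mRNA exposes
    one, so exclusion reads are doubled to put both isoforms on the same
    per-molecule footing.  ``weighting="simulated"`` divides by SJA + SJB
    (the simulator's native form).
    """
    missing = [c for c in JUNCTION_COLUMNS if c not in junction_table.columns]
    if missing:
        raise ValueError(f"junction table lacks columns {missing}")
    tab = junction_table
    if (tab["SJA"] < 0).any() or (tab["SJB"] < 0).any():
        raise ValueError("junction read counts must be non-negative")
    sja = tab.pivot_table(index="cell_id", columns="exon_id", values="SJA", aggfunc="sum").fillna(0)
    sjb = tab.pivot_table(index="cell_id", columns="exon_id", values="SJB", aggfunc="sum").fillna(0)
    sjb = sjb.reindex(index=sja.index, columns=sja.columns).fillna(0)
    denom = sja + 2.0 * sjb if weighting == "halved_exclusion" else sja + sjb
    psi = sja / denom
    psi[(sja + sjb) == 0] = np.nan
    return PsiEstimate(psi=psi, coverage=sja + sjb)


@dataclass
class CensusEstimate:
    """Per-cell Census quantities and the derived per-gene mRNA counts.

    total_mrna (Mi) may be NaN for cells flagged as degenerate or as
    >10-fold outliers versus the cohort median.
    """

    total_mrna: pd.Series  # Mi
    mode_tpm: pd.Series  # xi*
    n_mode_genes: pd.Series  # ni
    counts: pd.DataFrame  # Yig = Xig * Mi / 1e6
    flagged: pd.Series  # True where the cell was excluded


def _cell_census(values: np.ndarray, min_tpm: float, closed_mode: bool) -> tuple[float, float, int]:
    """Mi, xi*, ni for one cell from its nonzero TPM values."""
    nonzero = values[values > 0]
    expressed = nonzero[nonzero > min_tpm]
    if np.unique(expressed).size < 2:
        return np.nan, np.nan, 0
    logged = np.log(expressed)
    kde = stats.gaussian_kde(logged, bw_method="scott")
    grid = np.linspace(logged.min(), logged.max(), 512)
    x_star = float(np.exp(grid[np.argmax(kde(grid))]))
    if closed_mode:
        n_i = int(np.sum((nonzero > min_tpm) & (nonzero <= x_star)))
    else:
        n_i = int(np.sum((nonzero > min_tpm) & (nonzero < x_star)))
    # right-continuous empirical CDF over the cell's nonzero TPM values
    f_star = np.mean(nonzero <= x_star)
    f_min = np.mean(nonzero <= min_tpm)
    if f_star <= f_min:
        return np.nan, x_star, n_i
    m_i = n_i / (f_star - f_min)
    return float(m_i), x_star, n_i


def census_counts(
    tpm: pd.DataFrame,
    min_tpm: float = 0.1,
    mode_interval: Literal["closed", "open"] = "closed",
    outlier_fold: float = 10.0,
    min_read_quantile: float | None = None,
    total_reads: pd.Series | None = None,
) -> CensusEstimate:
    """Estimate captured mRNA counts per cell and gene from a TPM matrix.

    Mi = ni / (F(xi*) - F(min_tpm)) where xi* is the peak of a Gaussian
    kernel density over the cell's log-TPM values above ``min_tpm``, F is
    the right-continuous empirical CDF of the cell's detected (nonzero)
    TPM values, and ni counts genes with TPM in (min_tpm, xi*]
    (``mode_interval="open"`` uses the open right endpoint instead).
    Per-gene counts follow the exact identity Yig = Xig * Mi / 1e6.

    Cells with a degenerate TPM distribution, with Mi more than
    ``outlier_fold`` times the cohort median, or (optionally, when
    ``min_read_quantile``/``total_reads`` are given) in the bottom read
    quantile, are flagged and get NaN counts.
    """
    if (tpm.values < 0).any():
        raise ValueError("TPM matrix has negative entries")
    closed = mode_interval == "closed"
    rows = [_cell_census(row, min_tpm, closed) for row in tpm.to_numpy(dtype=float)]
    m_i = pd.Series([r[0] for r in rows], index=tpm.index, name="total_mrna")
    x_star = pd.Series([r[1] for r in rows], index=tpm.index, name="mode_tpm")
    n_i = pd.Series([r[2] for r in rows], index=tpm.index, name="n_mode_genes")

    flagged = m_i.isna()
    median = m_i[~flagged].median()
    if np.isfinite(median) and median > 0:
        flagged |= m_i > outlier_fold * median
    if min_read_quantile is not None:
        if total_reads is None:
            raise ValueError("min_read_quantile requires total_reads")
        cutoff = total_reads.reindex(tpm.index).quantile(min_read_quantile)
        flagged |= total_reads.reindex(tpm.index) <= cutoff
    m_kept = m_i.where(~flagged)
    counts = tpm.mul(m_kept, axis=0) / 1e6
    return CensusEstimate(m_kept, x_star, n_i, counts, flagged)


CONSTITUTIVE_COLUMNS = (
    "cell_id",
    "gene_id",
    "constitutive_junction_reads",
    "junctions_per_transcript",
)


def coverage_rate(
    constitutive_table: pd.DataFrame,
    census: CensusEstimate,
    min_mrna: float = 1.0,
) -> pd.Series:
    """Per-cell splice-junction coverage rate Cj (reads per junction per mRNA).

    Cj = sum_k r_jk / sum_k j_k * m_jk over the genes k estimated to carry
    at least ``min_mrna`` captured molecule(s) in cell j; r_jk are the
    reads on gene k's constitutive junctions, j_k the number of those
    junctions per transcript and m_jk the Census count.  Cells with an
    empty denominator get NaN.
    """
    missing = [c for c in CONSTITUTIVE_COLUMNS if c not in constitutive_table.columns]
    if missing:
        raise ValueError(f"constitutive table lacks columns {missing}")
    rates = {}
    counts = census.counts
    for cell, sub in constitutive_table.groupby("cell_id"):
        if cell not in counts.index:
            continue
        m = counts.loc[cell].reindex(sub["gene_id"]).to_numpy(dtype=float)
        ok = np.isfinite(m) & (m >= min_mrna)
        denom = float(np.sum(sub["junctions_per_transcript"].to_numpy(dtype=float)[ok] * m[ok]))
        if denom <= 0:
            rates[cell] = np.nan
            continue
        num = float(sub["constitutive_junction_reads"].to_numpy(dtype=float)[ok].sum())
        rates[cell] = num / denom
    return pd.Series(rates, name="coverage_rate").reindex(counts.index)


def filter_observations(
    psi: pd.DataFrame,
    coverage: pd.DataFrame,
    mrna_counts: pd.DataFrame,
    exon_gene: Mapping[str, str],
    cell_coverage_rate: pd.Series,
    min_mrna: float = 10.0,
) -> pd.DataFrame:
    """Boolean mask of observations backed by enough captured mRNA and reads.

    An observation (cell j, exon i) passes iff m_ij >= min_mrna and
    SJ_ij >= min_mrna * (1 + psi_hat_ij) * C_j — at least the junction
    reads expected were ``min_mrna`` molecules informative about the exon.
    Observations with missing psi_hat carry no information and fail.
    """
    genes = [exon_gene[e] for e in psi.columns]
    m_ij = mrna_counts.reindex(index=psi.index, columns=genes).to_numpy(dtype=float)
    c_j = cell_coverage_rate.reindex(psi.index).to_numpy(dtype=float)[:, None]
    psi_v = psi.to_numpy(dtype=float)
    sj = coverage.reindex(index=psi.index, columns=psi.columns).to_numpy(dtype=float)
    required = min_mrna * (1.0 + psi_v) * c_j
    with np.errstate(invalid="ignore"):
        ok = (m_ij >= min_mrna) & (sj >= required) & np.isfinite(psi_v)
    return pd.DataFrame(ok, index=psi.index, columns=psi.columns)


def cluster_retention(
    mask: pd.DataFrame,
    clusters: pd.Series,
    min_cell_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-cluster exon retention: pass-rate >= min_cell_fraction of cells."""
    clusters = clusters.reindex(mask.index)
    frac = mask.groupby(clusters, observed=True).mean()
    return frac >= min_cell_fraction


def baseline_filter(
    junction_table: pd.DataFrame,
    clusters: pd.Series,
    min_reads: float = 10.0,
    min_cell_fraction: float = 0.5,
) -> pd.DataFrame:
    """Flat benchmark: exon kept in a cluster iff >= min_reads junction reads
    in at least min_cell_fraction of the cluster's cells."""
    est = estimate_psi_from_junctions(junction_table)
    enough = est.coverage >= min_reads
    clusters = clusters.reindex(enough.index)
    frac = enough.groupby(clusters, observed=True).mean()
    return frac >= min_cell_fraction
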