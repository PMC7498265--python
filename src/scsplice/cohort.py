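"""Synthetic cohorts for the quantification and evaluation pipeline.

Builds, from the simulator, the exact input tables the quantification module
consumes on real data: a cells x genes TPM matrix, a long junction-count
table (SJA / SJB per cell and exon), a constitutive-junction calibration
table and cluster labels.  Optionally plants cluster-differential exons:
their underlying PSI distribution shifts between clusters while null exons
share one unimodal Beta law across all cells.

TPM values are derived from the simulated read counts as reads per kilobase
scaled to one million per cell, so expression is relative, as in real data,
and the Census step has real work to do.  Constitutive junction reads are
Poisson with the per-junction rate implied by the technical parameters
(depth_factor * 2 (lr - 1) / 1000 reads per junction per captured molecule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .sim_bio import (
    KineticsConfig,
    SplicingState,
    sample_exon_models,
    sample_kinetics,
    simulate_expression,
)
from .sim_tech import (
    JunctionReads,
    TechParams,
    capture_molecules,
    generate_reads,
    sample_junction_reads,
)

__all__ = [
    "SyntheticCohort",
    "TrajectoryPanel",
    "simulate_differential_cohort",
    "simulate_trajectory_panel",
    "junction_long_table",
]


@dataclass
class SyntheticCohort:
    """A simulated cohort packaged as quantification-pipeline inputs."""

    tpm: pd.DataFrame  # cells x genes
    junction_table: pd.DataFrame  # cell_id, exon_id, gene_id, SJA, SJB
    constitutive_table: pd.DataFrame
    clusters: pd.Series  # cell_id -> cluster label
    exon_gene: dict[str, str]
    differential: pd.Series  # exon_id -> planted differential flag
    state: SplicingState
    junctions: JunctionReads
    captured_total: pd.DataFrame  # true captured molecules per cell x gene
    exons: list


def junction_long_table(
    junctions: JunctionReads, exons, cell_ids, include_gene: bool = True
) -> pd.DataFrame:
    """Flatten simulated junction reads into the long table format."""
    n_cells, n_exons = junctions.inclusion_junction_reads.shape
    cell_col = np.repeat(np.asarray(cell_ids), n_exons)
    exon_col = np.tile([e.exon_id for e in exons], n_cells)
    out = pd.DataFrame(
        {
            "cell_id": cell_col,
            "exon_id": exon_col,
            "SJA": junctions.inclusion_junction_reads.ravel(),
            "SJB": junctions.exclusion_junction_reads.ravel(),
        }
    )
    if include_gene:
        out.insert(2, "gene_id", np.tile([e.gene_id for e in exons], n_cells))
    return out


def _planted_psi(
    rng: np.random.Generator,
    n_cells: int,
    cluster_of_cell: np.ndarray,
    n_clusters: int,
    effect: float,
    concentration: float,
) -> np.ndarray:
    """Per-cell PSI for one differential exon: cluster-shifted Beta draws."""
    base = rng.uniform(0.35, 0.65)
    offsets = (np.arange(n_clusters) - (n_clusters - 1) / 2.0) * effect
    means = np.clip(base + rng.permutation(offsets), 0.05, 0.95)
    mu = means[cluster_of_cell]
    return rng.beta(mu * concentration, (1.0 - mu) * concentration, size=n_cells)


DEFAULT_COHORT_KINETICS = KineticsConfig(k_on_log_mean=float(np.log(1.5)))


def simulate_differential_cohort(
    n_cells: int = 90,
    n_clusters: int = 3,
    n_differential: int = 75,
    n_null: int = 225,
    n_background: int = 6000,
    effect: float = 0.12,
    concentration: float = 30.0,
    tech: TechParams | None = None,
    kinetics_config: KineticsConfig | None = None,
    constitutive_junction_range: tuple[int, int] = (2, 10),
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a clustered cohort with planted differential splicing.

    ``n_differential`` exons shift their underlying mean PSI by ``effect``
    between adjacent clusters (cluster order shuffled per exon); ``n_null``
    exons keep one unimodal Beta law for all cells.  Expression, capture,
    sequencing and junction subsampling run through the standard simulator
    stages.

    The defaults place the planted effect in the coverage-limited regime
    the mRNA filter is designed for: a modest shift (0.12 between adjacent
    clusters) against a tight per-cell Beta (concentration 30, PSI noise
    ~0.09), so that whether the shift is detectable in a cluster of 30
    cells is governed by junction-read sampling noise — i.e. by how many
    mRNAs were captured — rather than by biological PSI dispersion.

    ``n_background`` additional genes without cassette exons fill out the
    transcriptome at low expression (scale LogNormal(ln 10, 1), so the
    modal detected gene carries about one captured molecule, as in real
    cells).  They anchor the mode of the log-TPM distribution that the
    Census estimate relies on and serve as constitutive-junction
    calibrators for the coverage rate; without them the cassette panel
    dominates the transcriptome and the Census count is badly deflated.
    """
    tech = tech or TechParams(junction_weighting="halved_exclusion")
    kinetics_config = kinetics_config or DEFAULT_COHORT_KINETICS
    n_exons = n_differential + n_null
    exons = sample_exon_models({"unimodal": n_exons}, rng_seed=seed)
    kinetics = sample_kinetics(
        n_exons, kinetics_config, rng_seed=seed, gene_ids=[e.gene_id for e in exons]
    )
    counts = simulate_expression(kinetics, n_cells, rng_seed=seed)

    cluster_of_cell = np.repeat(np.arange(n_clusters), int(np.ceil(n_cells / n_clusters)))[:n_cells]
    rng = stage_rng(seed, "psi")
    alpha = np.array([e.alpha for e in exons])
    beta = np.array([e.beta for e in exons])
    psi = rng.beta(alpha[None, :], beta[None, :], size=(n_cells, n_exons))
    diff_idx = rng.choice(n_exons, size=n_differential, replace=False)
    for j in diff_idx:
        psi[:, j] = _planted_psi(rng, n_cells, cluster_of_cell, n_clusters, effect, concentration)
    xa = rng.binomial(counts, psi)
    state = SplicingState(
        true_counts=counts, psi=psi, inclusion_counts=xa, exclusion_counts=counts - xa
    )

    captured = capture_molecules(state, tech, rng_seed=seed)
    l_a = np.array([e.inclusion_length for e in exons])
    l_b = np.array([e.exclusion_length for e in exons])
    reads = generate_reads(captured, l_a, l_b, tech, rng_seed=seed)
    junctions = sample_junction_reads(reads, exons, tech, rng_seed=seed)

    cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]
    gene_ids = [e.gene_id for e in exons]

    # background transcriptome: lowly expressed genes, captured and
    # sequenced through the same technical model (no cassette exon)
    rng_bg = stage_rng(seed, "misc")
    bg_ids = [f"bg_{i:05d}" for i in range(n_background)]
    bg_scale = rng_bg.lognormal(np.log(10.0), 1.0, n_background)
    bg_kon = rng_bg.lognormal(np.log(0.5), 1.0, n_background)
    bg_koff = rng_bg.lognormal(0.0, 1.0, n_background)
    bg_burst = rng_bg.beta(bg_kon[None, :], bg_koff[None, :], size=(n_cells, n_background))
    bg_counts = rng_bg.poisson(bg_scale[None, :] * bg_burst)
    bg_capture = rng_bg.binomial(bg_counts, tech.capture_mean)
    bg_lengths = np.clip(
        np.rint(rng_bg.lognormal(np.log(1900.0), 0.6, n_background)), 200, 20_000
    )
    bg_reads = rng_bg.poisson(bg_capture * tech.depth_factor * (bg_lengths[None, :] / 1000.0))

    # relative expression: reads per kilobase, scaled to 1e6 per cell
    rpk_cassette = reads.reads_inclusion / (l_a[None, :] / 1000.0) + reads.reads_exclusion / (
        l_b[None, :] / 1000.0
    )
    rpk_bg = bg_reads / (bg_lengths[None, :] / 1000.0)
    rpk = np.concatenate([rpk_cassette, rpk_bg], axis=1)
    totals = rpk.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    all_gene_ids = gene_ids + bg_ids
    tpm = pd.DataFrame(rpk / totals * 1e6, index=cell_ids, columns=all_gene_ids)

    # constitutive-junction calibration table over the whole transcriptome:
    # jk junctions per transcript, Poisson reads at the per-junction rate
    # implied by the tech parameters (one junction exposes 2(lr-1) read
    # start positions, depth_factor reads per molecule per kb)
    rng_const = stage_rng(seed, "constitutive")
    n_all = n_exons + n_background
    jk = rng_const.integers(
        constitutive_junction_range[0], constitutive_junction_range[1] + 1, size=n_all
    )
    per_junction_rate = tech.depth_factor * 2.0 * (tech.read_length - 1) / 1000.0
    captured_total = captured.captured_inclusion + captured.captured_exclusion
    captured_all = np.concatenate([captured_total, bg_capture], axis=1)
    rjk = rng_const.poisson(jk[None, :] * captured_all * per_junction_rate)
    constitutive = pd.DataFrame(
        {
            "cell_id": np.repeat(cell_ids, n_all),
            "gene_id": np.tile(all_gene_ids, n_cells),
            "constitutive_junction_reads": rjk.ravel(),
            "junctions_per_transcript": np.tile(jk, n_cells),
        }
    )

    junction_table = junction_long_table(junctions, exons, cell_ids)
    clusters = pd.Series(
        [f"cluster_{k}" for k in cluster_of_cell], index=cell_ids, name="cluster"
    )
    differential = pd.Series(False, index=[e.exon_id for e in exons], name="differential")
    differential.iloc[diff_idx] = True
    return SyntheticCohort(
        tpm=tpm,
        junction_table=junction_table,
        constitutive_table=constitutive,
        clusters=clusters,
        exon_gene={e.exon_id: e.gene_id for e in exons},
        differential=differential,
        state=state,
        junctions=junctions,
        captured_total=pd.DataFrame(captured_total, index=cell_ids, columns=gene_ids),
        exons=exons,
    )


@dataclass
class TrajectoryPanel:
    """Cells on a latent trajectory with PSI panels for autocorrelation tests.

    ``psi`` holds ``n_smooth`` exons whose PSI varies smoothly along the
    trajectory (random direction, base and amplitude per exon) followed by
    ``n_scrambled`` exons built the same way and then permuted across cells
    (destroying the smoothness while keeping the marginal distribution).
    ``expression`` contains trajectory-tracking genes plus flat noise genes,
    so a PCA embedding of it recovers the trajectory.
    """

    psi: pd.DataFrame
    expression: pd.DataFrame
    pseudotime: np.ndarray
    smooth: pd.Series  # exon_id -> True for trajectory-smooth exons


def simulate_trajectory_panel(
    n_cells: int = 120,
    n_smooth: int = 50,
    n_scrambled: int = 200,
    concentration: float = 20.0,
    n_trajectory_genes: int = 30,
    n_noise_genes: int = 70,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> TrajectoryPanel:
    """Simulate a latent-trajectory cohort for the autocorrelation test."""
    rng = stage_rng(seed, "misc", 1)
    t = np.sort(rng.uniform(0.0, 1.0, n_cells))

    half = n_trajectory_genes // 2
    up = rng.poisson(5 + 60 * t[:, None], size=(n_cells, half))
    down = rng.poisson(5 + 60 * (1 - t)[:, None], size=(n_cells, n_trajectory_genes - half))
    noise = rng.poisson(20, size=(n_cells, n_noise_genes))
    expression = pd.DataFrame(
        np.column_stack([up, down, noise]),
        index=[f"cell_{i:04d}" for i in range(n_cells)],
        columns=[f"gene_{j:04d}" for j in range(n_trajectory_genes + n_noise_genes)],
    )

    def smooth_mu() -> np.ndarray:
        sign = rng.choice([-1.0, 1.0])
        base = rng.uniform(0.35, 0.65)
        amp = rng.uniform(0.3, 0.5)
        return np.clip(base + sign * amp * (t - 0.5), 0.02, 0.98)

    cols: dict[str, np.ndarray] = {}
    flags = {}
    for j in range(n_smooth):
        mu = smooth_mu()
        cols[f"smooth_{j:04d}"] = rng.beta(mu * concentration, (1 - mu) * concentration)
        flags[f"smooth_{j:04d}"] = True
    for j in range(n_scrambled):
        mu = smooth_mu()
        v = rng.beta(mu * concentration, (1 - mu) * concentration)
        cols[f"scrambled_{j:04d}"] = rng.permutation(v)
        flags[f"scrambled_{j:04d}"] = False
    psi = pd.DataFrame(cols, index=expression.index)
    if missing_fraction > 0:
        drop = rng.random(psi.shape) < missing_fraction
        psi = psi.mask(drop)
    return TrajectoryPanel(
        psi=psi,
        expression=expression,
        pseudotime=t,
        smooth=pd.Series(flags, name="smooth"),
    )
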