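"""Seeded experiment drivers.

These reproduce the simulator's designed experiments:

* ``sweep_expression`` — fixed underlying PSI, expression of gene g fixed at
  g molecules in every cell, mean capture 0.1; measures how the proportion
  of binary observations (PSI-hat exactly 0 or 1) falls with expression.
  ``expression_at_half_binary`` reads off the smallest expression level at
  which that proportion reaches one half.
* ``sweep_capture`` — realized inclusion fraction pinned to 1/2
  (XA = XB = X/2), capture efficiency swept; measures binary proportions by
  junction-read coverage rank.
* ``run_regime_comparison`` — bimodal vs unimodal cohorts under shared
  seeds at a grid of capture efficiencies, with per-exon binary proportion
  vs coverage and 21-bin PSI histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .sim_bio import LengthConfig, sample_exon_models
from .sim_tech import (
    SimulationConfig,
    SimulationResult,
    TechParams,
    junction_probabilities,
    run_simulation,
)

__all__ = [
    "ExperimentConfig",
    "sweep_expression",
    "expression_at_half_binary",
    "sweep_capture",
    "run_regime_comparison",
    "psi_histograms",
]

PAPER_PSI_GRID = tuple(np.round(np.arange(0.01, 0.501, 0.01), 2))
PAPER_CAPTURE_GRID = tuple(np.round(np.arange(0.01, 0.1001, 0.001), 3))


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the sweep experiments.

    Defaults follow the fixed-expression design: 300 cells, 500 genes with
    the expression of gene g pinned to g molecules in every cell, mean
    capture efficiency 0.1, 30 replicate simulations per condition.
    """

    n_cells: int = 300
    n_genes: int = 500
    tech: TechParams = field(default_factory=lambda: TechParams(capture_mean=0.1))
    length_config: LengthConfig = field(default_factory=LengthConfig)
    psi_grid: tuple[float, ...] = PAPER_PSI_GRID
    capture_grid: tuple[float, ...] = PAPER_CAPTURE_GRID
    n_replicates: int = 30
    seed: int = 0


def _binary_and_observed(sja: np.ndarray, sjb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    observed = (sja + sjb) > 0
    binary = observed & ((sja == 0) | (sjb == 0))
    return binary, observed


def sweep_expression(config: ExperimentConfig) -> pd.DataFrame:
    """Binary-observation proportion by (underlying PSI, expression level).

    For each PSI on the grid and each replicate, every cell expresses gene
    g at exactly g molecules, splices at the fixed PSI, and passes through
    capture, sequencing and junction subsampling.  The output averages the
    indicator of a binary observation over cells and replicates among
    non-missing observations (binary status does not depend on the junction
    weighting).  Columns: psi, expression, binary_proportion, n_obs.
    """
    n_cells, n_genes = config.n_cells, config.n_genes
    expression = np.tile(np.arange(1, n_genes + 1), (n_cells, 1))
    # one exon panel per experiment; the junction-read rates depend on
    # length only through the (lr-1)/l cancellation, but the panel is drawn
    # once so replicates share gene identities
    exons = sample_exon_models(
        {"unimodal": n_genes}, config.length_config, rng_seed=config.seed
    )
    j_a, j_b = junction_probabilities(exons, config.tech.read_length)
    l_a = np.array([e.inclusion_length for e in exons], dtype=float)
    l_b = np.array([e.exclusion_length for e in exons], dtype=float)
    depth = config.tech.depth_factor
    rows = []
    for psi in config.psi_grid:
        binary_sum = np.zeros(n_genes)
        obs_sum = np.zeros(n_genes)
        for rep in range(config.n_replicates):
            rng = stage_rng(config.seed, "misc", _rep_key(psi, rep))
            xa = rng.binomial(expression, psi)
            xb = expression - xa
            p_a = _trunc_probs(rng, config.tech, (n_cells, n_genes))
            p_b = _trunc_probs(rng, config.tech, (n_cells, n_genes))
            ca = rng.binomial(xa, p_a)
            cb = rng.binomial(xb, p_b)
            ra = rng.poisson(ca * depth * (l_a[None, :] / 1000.0))
            rb = rng.poisson(cb * depth * (l_b[None, :] / 1000.0))
            sja = rng.binomial(ra, j_a[None, :])
            sjb = rng.binomial(rb, j_b[None, :])
            binary, observed = _binary_and_observed(sja, sjb)
            binary_sum += binary.sum(axis=0)
            obs_sum += observed.sum(axis=0)
        with np.errstate(invalid="ignore"):
            prop = binary_sum / obs_sum
        for g in range(n_genes):
            rows.append((psi, g + 1, prop[g], int(obs_sum[g])))
    return pd.DataFrame(rows, columns=["psi", "expression", "binary_proportion", "n_obs"])


def _rep_key(psi: float, rep: int) -> int:
    # distinct replicate substream per (psi, replicate) pair
    return int(round(psi * 1000)) * 1000 + rep


def _trunc_probs(rng: np.random.Generator, tech: TechParams, shape) -> np.ndarray:
    from .sim_tech import _truncnorm_probs

    return _truncnorm_probs(rng, tech.capture_mean, tech.capture_variance, shape)


def expression_at_half_binary(
    sweep: pd.DataFrame, psi: float, level: float = 0.5
) -> int | None:
    """Smallest expression level at which the mean binary proportion drops
    to ``level`` for the given underlying PSI; None if it never does."""
    sub = sweep[np.isclose(sweep["psi"], psi)].sort_values("expression")
    hit = sub[sub["binary_proportion"] <= level]
    if hit.empty:
        return None
    return int(hit["expression"].iloc[0])


def sweep_capture(config: ExperimentConfig) -> pd.DataFrame:
    """Binary proportion by (capture efficiency, junction-coverage rank).

    The realized inclusion fraction of every exon is pinned to exactly 1/2
    (expression rounded down to even, XA = XB = X/2), removing the
    underlying-PSI contribution; capture efficiency is swept over the grid.
    Exons are ranked (1 = highest) by total informative junction reads.
    Columns: capture, exon_rank, exon_id, binary_proportion, mean_coverage.
    """
    rows = []
    for ci, c in enumerate(config.capture_grid):
        sim_config = SimulationConfig(
            n_cells=config.n_cells,
            n_per_regime={"unimodal": config.n_genes},
            tech=replace(config.tech, capture_mean=float(c)),
            length_config=config.length_config,
            seed=config.seed,
            fixed_ratio=0.5,
        )
        result = run_simulation(sim_config, replicate=ci)
        sja = result.junctions.inclusion_junction_reads
        sjb = result.junctions.exclusion_junction_reads
        binary, observed = _binary_and_observed(sja, sjb)
        with np.errstate(invalid="ignore"):
            prop = binary.sum(0) / observed.sum(0)
        coverage = (sja + sjb).mean(axis=0)
        order = np.argsort(-coverage, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        for g, exon in enumerate(result.exons):
            rows.append((float(c), int(ranks[g]), exon.exon_id, prop[g], coverage[g]))
    return pd.DataFrame(
        rows, columns=["capture", "exon_rank", "exon_id", "binary_proportion", "mean_coverage"]
    )


def psi_histograms(psi: np.ndarray, n_bins: int = 21) -> np.ndarray:
    """Per-exon histograms of PSI across cells on a fixed [0, 1] grid."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = np.zeros((psi.shape[1], n_bins), dtype=int)
    for j in range(psi.shape[1]):
        v = psi[:, j]
        v = v[np.isfinite(v)]
        out[j] = np.histogram(v, bins=edges)[0]
    return out


@dataclass
class RegimeRun:
    capture: float
    result: SimulationResult
    exon_table: pd.DataFrame  # per-exon binary proportion / coverage / mean psi
    psi_hist: np.ndarray
    psi_hat_hist: np.ndarray


def _exon_table(result: SimulationResult) -> pd.DataFrame:
    sja = result.junctions.inclusion_junction_reads
    sjb = result.junctions.exclusion_junction_reads
    binary, observed = _binary_and_observed(sja, sjb)
    with np.errstate(invalid="ignore"):
        prop = binary.sum(0) / observed.sum(0)
    coverage = (sja + sjb).mean(axis=0)
    psi_hat = result.junctions.observed_psi
    obs_mask = np.isfinite(psi_hat)
    with np.errstate(invalid="ignore"):
        mean_obs = np.where(obs_mask, psi_hat, 0.0).sum(0) / obs_mask.sum(0)
    return pd.DataFrame(
        {
            "exon_id": [e.exon_id for e in result.exons],
            "regime": [e.regime.value for e in result.exons],
            "alpha": [e.alpha for e in result.exons],
            "beta": [e.beta for e in result.exons],
            "mean_true_psi": np.nanmean(result.state.psi, axis=0),
            "mean_observed_psi": mean_obs,
            "binary_proportion": prop,
            "mean_coverage": coverage,
            "n_observed": observed.sum(0),
        }
    )


def run_regime_comparison(
    capture_grid: Sequence[float] = (0.025, 0.1),
    n_cells: int = 300,
    n_alternative: int = 500,
    n_constitutive: int = 500,
    tech: TechParams | None = None,
    seed: int = 0,
) -> dict[str, list[RegimeRun]]:
    """Bimodal vs unimodal cohorts under shared seeds at each capture level.

    Each cohort has ``n_alternative`` alternatively spliced exons plus
    ``n_constitutive`` consistently included and as many consistently
    excluded exons.  Returns per-regime lists of runs, one per capture
    efficiency, with per-exon summary tables and 21-bin PSI histograms.
    """
    from .sim_bio import sample_kinetics, sample_true_splicing, simulate_expression
    from .sim_tech import capture_molecules, generate_reads, sample_junction_reads

    tech = tech or TechParams()
    out: dict[str, list[RegimeRun]] = {}
    for regime in ("bimodal", "unimodal"):
        n_per_regime = {
            regime: n_alternative,
            "included": n_constitutive,
            "excluded": n_constitutive,
        }
        # the biological state is drawn once per regime; capture levels share
        # it so differences between runs are purely technical
        exons = sample_exon_models(n_per_regime, rng_seed=seed)
        kinetics = sample_kinetics(len(exons), rng_seed=seed, gene_ids=[e.gene_id for e in exons])
        counts = simulate_expression(kinetics, n_cells, rng_seed=seed)
        state = sample_true_splicing(exons, counts, rng_seed=seed)
        l_a = np.array([e.inclusion_length for e in exons])
        l_b = np.array([e.exclusion_length for e in exons])
        runs = []
        for ci, c in enumerate(capture_grid):
            params = replace(tech, capture_mean=float(c))
            captured = capture_molecules(state, params, rng_seed=seed, replicate=ci)
            reads = generate_reads(captured, l_a, l_b, params, rng_seed=seed, replicate=ci)
            junctions = sample_junction_reads(reads, exons, params, rng_seed=seed, replicate=ci)
            cfg = SimulationConfig(n_cells=n_cells, n_per_regime=n_per_regime, tech=params, seed=seed)
            result = SimulationResult(
                cfg, list(exons), state, captured, reads, junctions,
                {"seed": seed, "capture_mean": float(c), "regime": regime},
            )
            runs.append(
                RegimeRun(
                    capture=float(c),
                    result=result,
                    exon_table=_exon_table(result),
                    psi_hist=psi_histograms(state.psi),
                    psi_hat_hist=psi_histograms(junctions.observed_psi),
                )
            )
        out[regime] = runs
    return out
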