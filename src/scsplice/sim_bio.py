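"""Biological layer of the splicing simulator.

Simulates, per cell, the expression of a set of genes and the splicing of one
cassette exon per gene.  The per-cell splicing rate of exon ``j`` is drawn
from a Beta distribution with exon-specific shapes ``(alpha_j, beta_j)``;
molecule counts of the inclusion isoform are a binomial sample from the
gene's transcript count.  The Beta shapes define four splicing regimes:

* ``bimodal``  — alpha, beta < 1: cells sit near PSI 0 or 1.
* ``unimodal`` — alpha, beta > 1: interior mode, both isoforms co-occur.
* ``included`` — mode at 1 (alpha >= 1 > beta).
* ``excluded`` — mode at 0 (beta >= 1 > alpha).

Gene expression uses a two-state transcriptional-bursting stand-in: the
burst fraction is Beta(k_on, k_off) and the count Poisson(scale * fraction),
so the per-gene mean is scale * k_on / (k_on + k_off).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rng import stage_rng

__all__ = [
    "Regime",
    "ExonModel",
    "BurstKinetics",
    "LengthConfig",
    "KineticsConfig",
    "SplicingState",
    "sample_exon_models",
    "sample_kinetics",
    "simulate_expression",
    "sample_true_splicing",
]


class ConfigurationError(ValueError):
    """Raised when simulator parameters are inconsistent or out of range."""


class Regime(str, enum.Enum):
    BIMODAL = "bimodal"
    UNIMODAL = "unimodal"
    INCLUDED = "included"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class ExonModel:
    """One cassette exon: Beta shapes, regime label and isoform lengths (nt).

    ``inclusion_length`` is the length of the isoform that includes the exon
    and always equals ``exclusion_length + exon_length``.
    """

    exon_id: str
    gene_id: str
    alpha: float
    beta: float
    regime: Regime
    exclusion_length: int
    exon_length: int
    inclusion_length: int

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigurationError(
                f"{self.exon_id}: Beta shapes must be positive "
                f"(alpha={self.alpha}, beta={self.beta})"
            )
        if self.exclusion_length <= 0 or self.exon_length <= 0:
            raise ConfigurationError(f"{self.exon_id}: lengths must be positive")
        if self.inclusion_length != self.exclusion_length + self.exon_length:
            raise ConfigurationError(
                f"{self.exon_id}: inclusion_length must equal "
                "exclusion_length + exon_length"
            )

    @property
    def mean_psi(self) -> float:
        """Population mean of the underlying splicing rate, alpha/(alpha+beta)."""
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class BurstKinetics:
    """Two-state transcription parameters of one gene."""

    gene_id: str
    k_on: float
    k_off: float
    scale: float

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off) <= 0 or self.scale < 0:
            raise ConfigurationError(
                f"{self.gene_id}: burst rates must be strictly positive "
                "and scale non-negative"
            )


@dataclass(frozen=True)
class LengthConfig:
    """Stand-in isoform/exon length laws (log-normal, clipped, integer nt).

    Defaults mimic human transcript and skipped-exon length scales: the
    exclusion-isoform length is LogNormal(ln 1900, 0.6) clipped to
    [200, 20000] nt and the cassette-exon length LogNormal(ln 120, 0.5)
    clipped to [25, 2000] nt.  External length tables may be supplied to
    draw from instead (without replacement when long enough).
    """

    exclusion_log_mean: float = float(np.log(1900.0))
    exclusion_log_sd: float = 0.6
    exclusion_clip: tuple[int, int] = (200, 20_000)
    exon_log_mean: float = float(np.log(120.0))
    exon_log_sd: float = 0.5
    exon_clip: tuple[int, int] = (25, 2_000)
    exclusion_table: Sequence[int] | None = None
    exon_table: Sequence[int] | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.exclusion_clip, self.exon_clip):
            if lo <= 0 or hi <= lo:
                raise ConfigurationError("length clip bounds must be positive and ordered")

    def _draw(self, rng: np.random.Generator, n: int, which: str) -> np.ndarray:
        table = self.exclusion_table if which == "exclusion" else self.exon_table
        if table is not None:
            arr = np.asarray(table, dtype=int)
            if np.any(arr <= 0):
                raise ConfigurationError("external length table has non-positive entries")
            replace = len(arr) < n
            return rng.choice(arr, size=n, replace=replace)
        if which == "exclusion":
            mu, sd, clip = self.exclusion_log_mean, self.exclusion_log_sd, self.exclusion_clip
        else:
            mu, sd, clip = self.exon_log_mean, self.exon_log_sd, self.exon_clip
        raw = rng.lognormal(mean=mu, sigma=sd, size=n)
        return np.clip(np.rint(raw), clip[0], clip[1]).astype(int)


@dataclass(frozen=True)
class KineticsConfig:
    """Hyper-priors for per-gene bursting parameters (log-normal)."""

    k_on_log_mean: float = float(np.log(0.5))
    k_on_log_sd: float = 1.0
    k_off_log_mean: float = 0.0
    k_off_log_sd: float = 1.0
    scale_log_mean: float = float(np.log(50.0))
    scale_log_sd: float = 1.5


@dataclass
class SplicingState:
    """True (pre-observation) molecule counts and splicing rates.

    ``true_ratio`` is the realized per-cell inclusion fraction
    XA / X; it is NaN where the gene has zero molecules (0/0 carries no
    splicing information and is excluded from every average downstream).
    """

    true_counts: np.ndarray  # cells x genes, int
    psi: np.ndarray  # cells x exons, float in [0, 1]
    inclusion_counts: np.ndarray  # cells x exons, int
    exclusion_counts: np.ndarray  # cells x exons, int
    true_ratio: np.ndarray = field(init=False)  # cells x exons, float, NaN if X == 0

    def __post_init__(self) -> None:
        x = self.true_counts
        if np.any(self.inclusion_counts + self.exclusion_counts != x):
            raise ValueError("inclusion + exclusion counts must equal true counts")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = self.inclusion_counts / x.astype(float)
        ratio[x == 0] = np.nan
        self.true_ratio = ratio

    @property
    def n_cells(self) -> int:
        return self.true_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.true_counts.shape[1]


_REGIME_ORDER = (Regime.BIMODAL, Regime.UNIMODAL, Regime.INCLUDED, Regime.EXCLUDED)


def _draw_shapes(rng: np.random.Generator, regime: Regime, n: int) -> tuple[np.ndarray, np.ndarray]:
    if regime is Regime.BIMODAL:
        return 1.0 / rng.uniform(1, 30, n), 1.0 / rng.uniform(1, 30, n)
    if regime is Regime.UNIMODAL:
        return rng.uniform(1, 30, n), rng.uniform(1, 30, n)
    if regime is Regime.INCLUDED:
        return rng.uniform(1, 30, n), 1.0 / rng.uniform(1, 5, n)
    if regime is Regime.EXCLUDED:
        return 1.0 / rng.uniform(1, 5, n), rng.uniform(1, 30, n)
    raise ConfigurationError(f"unknown regime {regime!r}")


def sample_exon_models(
    n_per_regime: Mapping[Regime | str, int],
    length_config: LengthConfig | None = None,
    rng_seed: int = 0,
) -> list[ExonModel]:
    """Draw exon models for each requested splicing regime.

    Beta shapes follow the regime-specific laws (bimodal: both shapes are
    reciprocals of Uniform(1, 30) draws; unimodal: Uniform(1, 30) draws;
    included/excluded: the asymmetric Uniform(1, 30) vs 1/Uniform(1, 5)
    laws).  Lengths come from :class:`LengthConfig`.
    """
    length_config = length_config or LengthConfig()
    rng = stage_rng(rng_seed, "exons")
    counts = {Regime(k): int(v) for k, v in n_per_regime.items()}
    if any(v < 0 for v in counts.values()):
        raise ConfigurationError("regime counts must be non-negative")
    exons: list[ExonModel] = []
    idx = 0
    for regime in _REGIME_ORDER:
        n = counts.get(regime, 0)
        if n == 0:
            continue
        alpha, beta = _draw_shapes(rng, regime, n)
        l_excl = length_config._draw(rng, n, "exclusion")
        l_exon = length_config._draw(rng, n, "exon")
        for a, b, le, lx in zip(alpha, beta, l_excl, l_exon):
            exons.append(
                ExonModel(
                    exon_id=f"exon_{idx:05d}",
                    gene_id=f"gene_{idx:05d}",
                    alpha=float(a),
                    beta=float(b),
                    regime=regime,
                    exclusion_length=int(le),
                    exon_length=int(lx),
                    inclusion_length=int(le) + int(lx),
                )
            )
            idx += 1
    return exons


def sample_kinetics(
    n_genes: int,
    config: KineticsConfig | None = None,
    rng_seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> list[BurstKinetics]:
    """Draw per-gene bursting parameters from the log-normal hyper-priors."""
    config = config or KineticsConfig()
    rng = stage_rng(rng_seed, "kinetics")
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ConfigurationError("gene_ids length must equal n_genes")
    k_on = rng.lognormal(config.k_on_log_mean, config.k_on_log_sd, n_genes)
    k_off = rng.lognormal(config.k_off_log_mean, config.k_off_log_sd, n_genes)
    scale = rng.lognormal(config.scale_log_mean, config.scale_log_sd, n_genes)
    return [
        BurstKinetics(g, float(a), float(b), float(s))
        for g, a, b, s in zip(gene_ids, k_on, k_off, scale)
    ]


def simulate_expression(
    kinetics: Sequence[BurstKinetics],
    n_cells: int,
    rng_seed: int = 0,
    replicate: int = 0,
) -> np.ndarray:
    """Simulate a cells x genes matrix of transcript counts.

    Each entry is Poisson(scale * B) with B ~ Beta(k_on, k_off) drawn
    independently per cell, i.e. a Beta-Poisson bursting model.
    """
    if not kinetics:
        raise ConfigurationError("kinetics list must not be empty")
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = stage_rng(rng_seed, "expression", replicate)
    k_on = np.array([k.k_on for k in kinetics])
    k_off = np.array([k.k_off for k in kinetics])
    scale = np.array([k.scale for k in kinetics])
    burst = rng.beta(k_on[None, :], k_off[None, :], size=(n_cells, len(kinetics)))
    return rng.poisson(scale[None, :] * burst)


def sample_true_splicing(
    exons: Sequence[ExonModel],
    true_counts: np.ndarray,
    rng_seed: int = 0,
    fixed_psi: float | None = None,
    fixed_ratio: float | None = None,
    replicate: int = 0,
) -> SplicingState:
    """Draw per-cell splicing rates and isoform molecule counts.

    One cassette exon per gene: exon ``j`` maps to gene column ``j`` of
    ``true_counts``.  ``fixed_psi`` bypasses the Beta draw (the splicing
    rate is constant; isoform counts stay binomial).  ``fixed_ratio``
    additionally pins the realized inclusion fraction: XA = ratio * X
    exactly, which requires ratio * X to be integral in every entry.
    """
    true_counts = np.asarray(true_counts)
    n_cells, n_genes = true_counts.shape
    if len(exons) != n_genes:
        raise ConfigurationError(
            f"{len(exons)} exons but {n_genes} gene columns; expected a bijection"
        )
    if np.any(true_counts < 0):
        raise ConfigurationError("true counts must be non-negative")
    rng = stage_rng(rng_seed, "psi", replicate)

    if fixed_ratio is not None:
        xa_exact = fixed_ratio * true_counts
        xa = np.rint(xa_exact).astype(int)
        if not np.allclose(xa, xa_exact):
            raise ConfigurationError(
                "fixed_ratio * true_counts must be integral in every entry "
                "(round expression to a compatible value first)"
            )
        psi = np.full((n_cells, n_genes), float(fixed_ratio))
    else:
        if fixed_psi is not None:
            if not 0.0 <= fixed_psi <= 1.0:
                raise ConfigurationError("fixed_psi must lie in [0, 1]")
            psi = np.full((n_cells, n_genes), float(fixed_psi))
        else:
            alpha = np.array([e.alpha for e in exons])
            beta = np.array([e.beta for e in exons])
            psi = rng.beta(alpha[None, :], beta[None, :], size=(n_cells, n_genes))
        xa = rng.binomial(true_counts, psi)
    xb = true_counts - xa
    return SplicingState(
        true_counts=true_counts,
        psi=psi,
        inclusion_counts=xa,
        exclusion_counts=xb,
    )
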