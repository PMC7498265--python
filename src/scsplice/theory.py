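"""Closed-form theory of observed PSI under limited mRNA capture.

A gene has ``m`` transcripts in a cell, a fraction ``psi`` of which include
the cassette exon.  Capture recovers ``r`` of them uniformly at random
(without replacement), so the observed inclusion fraction psi_hat = a / r
follows a hypergeometric law.  When only the capture efficiency ``c`` is
known, ``m`` is marginalized under a uniform prior: the posterior
Pr(m | r, c) = C(m, r) c^(r+1) (1-c)^(m-r) is a shifted negative binomial.
Conditioning instead on detection (r > 0) and a known ``m`` gives the
distribution used to ask how many molecules a gene needs before its
splicing rate can be estimated at all.

All probability-mass functions are returned as ``{psi_hat: probability}``
dictionaries over the achievable support.  ``binary_probability`` sums the
mass at exactly 0 and 1 — the probability of observing only one isoform.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "psi_hat_pmf_given_m_r",
    "posterior_m_given_r_c",
    "capture_normalization_sum",
    "psi_hat_pmf_given_r_c",
    "prob_within_delta",
    "psi_hat_pmf_given_m_c_detected",
    "binary_probability",
]


def _round_m_psi(psi: float, m: int, rounding: bool) -> int:
    exact = psi * m
    nearest = float(np.round(exact))  # banker's rounding at .5 ties
    if abs(exact - nearest) > 1e-9 and not rounding:
        raise ValueError(
            f"m * psi = {exact} is not an integer; pass rounding=True to opt in "
            "to nearest-integer rounding"
        )
    return int(nearest)


def psi_hat_pmf_given_m_r(
    psi: float, r: int, m: int, rounding: bool = False
) -> dict[float, float]:
    """Exact pmf of psi_hat given the transcript count m and capture count r.

    Hypergeometric: a of the r captured molecules carry the inclusion
    isoform, out of m*psi inclusion molecules among m total.
    """
    if not 0 <= r <= m:
        raise ValueError("need 0 <= r <= m")
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must be in [0, 1]")
    k_incl = _round_m_psi(psi, m, rounding)
    if r == 0:
        return {}
    a = np.arange(r + 1)
    probs = stats.hypergeom.pmf(a, m, k_incl, r)
    return {float(ai) / r: float(p) for ai, p in zip(a, probs) if p > 0.0}


def posterior_m_given_r_c(m: int, r: int, c: float) -> float:
    """Posterior probability of m total transcripts given r captured at rate c.

    Under a uniform prior on m, Pr(m | r, c) = C(m, r) c^(r+1) (1-c)^(m-r);
    the normalizing constant of the binomial likelihood over m is exactly 1/c.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError("capture rate c must be in (0, 1] (c=0 gives an improper posterior)")
    if m < r or r < 0:
        raise ValueError("need m >= r >= 0")
    if c == 1.0:
        return 1.0 if m == r else 0.0
    log_p = (
        gammaln(m + 1)
        - gammaln(r + 1)
        - gammaln(m - r + 1)
        + (r + 1) * math.log(c)
        + (m - r) * math.log1p(-c)
    )
    return float(np.exp(log_p))


def capture_normalization_sum(
    r: int, c: float, rtol: float = 1e-9, max_terms: int = 10_000_000
) -> float:
    """Numerically sum the capture likelihood over m >= r.

    Returns sum_m C(m, r) c^r (1-c)^(m-r), which equals 1/c analytically;
    the sum is extended adaptively until the negative-binomial tail mass
    drops below ``rtol``.  Exposed as an independent check of the 1/c
    normalizing identity.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError("c must be in (0, 1]")
    if c == 1.0:
        return 1.0
    # tail beyond k failures is nbinom.sf(k, r+1, c) / c in likelihood units
    k_max = int(stats.nbinom.isf(rtol * c, r + 1, c)) + 10
    k_max = min(k_max, max_terms)
    k = np.arange(k_max + 1)
    log_terms = (
        gammaln(r + k + 1)
        - gammaln(r + 1)
        - gammaln(k + 1)
        + r * math.log(c)
        + k * math.log1p(-c)
    )
    return float(np.exp(log_terms).sum())


def _m_cap(r: int, c: float, m_max: int | None, tail_tol: float | None) -> int:
    cap = int(math.ceil(10.0 * r / c)) if m_max is None else int(m_max)
    if m_max is None and tail_tol is not None:
        # extend the 10r/c cap while posterior tail mass exceeds tail_tol
        needed = r + int(stats.nbinom.isf(tail_tol, r + 1, c)) + 1
        cap = max(cap, needed)
    return cap


def psi_hat_pmf_given_r_c(
    psi: float,
    r: int,
    c: float,
    m_max: int | None = None,
    tail_tol: float | None = 1e-9,
) -> dict[float, float]:
    """pmf of psi_hat given r captured molecules and capture rate c.

    Marginalizes the unknown transcript count m over its posterior,
    truncating the sum at ten times the posterior mean r/c (extended
    adaptively while the truncated tail mass exceeds ``tail_tol``).
    Non-integer m*psi inside the sum is rounded to the nearest integer.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if not 0.0 < c <= 1.0:
        raise ValueError("c must be in (0, 1]")
    if c == 1.0:
        return psi_hat_pmf_given_m_r(psi, r, r, rounding=True)
    cap = _m_cap(r, c, m_max, tail_tol)
    m = np.arange(r, cap + 1)
    k_incl = np.round(psi * m).astype(int)
    log_post = (
        gammaln(m + 1)
        - gammaln(r + 1)
        - gammaln(m - r + 1)
        + (r + 1) * math.log(c)
        + (m - r) * math.log1p(-c)
    )
    post = np.exp(log_post)
    a = np.arange(r + 1)
    # hypergeom pmf for every (a, m) pair, vectorized
    hyp = stats.hypergeom.pmf(a[:, None], m[None, :], k_incl[None, :], r)
    probs = hyp @ post
    return {float(ai) / r: float(p) for ai, p in zip(a, probs)}


def prob_within_delta(
    psi: float,
    r: int,
    c: float,
    delta: float,
    m_max: int | None = None,
    tail_tol: float | None = 1e-9,
) -> float:
    """Probability that |psi_hat - psi| < delta given r captured molecules."""
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    pmf = psi_hat_pmf_given_r_c(psi, r, c, m_max=m_max, tail_tol=tail_tol)
    return float(sum(p for v, p in pmf.items() if abs(v - psi) < delta))


def psi_hat_pmf_given_m_c_detected(
    psi: float, c: float, m: int, rounding: bool = False
) -> dict[float, float]:
    """pmf of psi_hat given m transcripts and capture rate c, conditioned on
    the gene being detected (at least one molecule captured).

    Marginalizes the capture count r from 1 to m: hypergeometric composition
    times binomial capture, normalized by Pr(detected) = 1 - (1-c)^m.
    psi_hat values from different r are pooled exactly (as rationals a/r).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < c <= 1.0:
        raise ValueError("c must be in (0, 1]")
    k_incl = _round_m_psi(psi, m, rounding)
    detect = 1.0 - (1.0 - c) ** m
    acc: dict[Fraction, float] = {}
    r_all = np.arange(1, m + 1)
    binom_r = stats.binom.pmf(r_all, m, c)
    for r, pr in zip(r_all, binom_r):
        if pr <= 0.0:
            continue
        a = np.arange(r + 1)
        hyp = stats.hypergeom.pmf(a, m, k_incl, int(r))
        for ai, p in zip(a, hyp):
            if p <= 0.0:
                continue
            key = Fraction(int(ai), int(r))
            acc[key] = acc.get(key, 0.0) + float(pr * p)
    return {float(k): v / detect for k, v in sorted(acc.items())}


def binary_probability(pmf: Mapping[float, float]) -> float:
    """Mass of a psi_hat pmf at exactly 0 or exactly 1 (one isoform observed)."""
    return float(sum(p for v, p in pmf.items() if v == 0.0 or v == 1.0))
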