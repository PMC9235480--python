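"""Read-count likelihoods under the binary-genotype error model.

The model distinguishes the *true* genotype g ∈ {0,1} of a cell at a locus
from the *library* genotype ψ ∈ {0,1} actually represented in the sequencing
library after whole-genome amplification. Library preparation flips genotypes
with global false-positive rate α (P(ψ=1|g=0)) and false-negative rate β
(P(ψ=0|g=1)). Given ψ, the variant read count v out of c = r + v total reads
is binomial with success probability μ0 (reference library genotype,
sequencing error level) or μ1 (mutant library genotype, 0.5 for a
heterozygous site on a diploid).

Marginalizing ψ gives the per-entry log-likelihood

    log P(r,v|g) = log C(c,v)
                 + (1-g)·log{ μ0^v (1-μ0)^r (1-α) + μ1^v (1-μ1)^r α }
                 +   g  ·log{ μ0^v (1-μ0)^r β     + μ1^v (1-μ1)^r (1-β) },

evaluated here in log space with log-sum-exp so that extreme coverages and
boundary rates (α, β ∈ {0,1}) return -inf rather than underflow or NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

__all__ = [
    "ErrorRates",
    "ModelParams",
    "LikelihoodTables",
    "entry_loglik",
    "build_tables",
    "total_loglik",
]


@dataclass(frozen=True)
class ErrorRates:
    """Global genotype error rates: false positive ``alpha``, false negative ``beta``."""

    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError(f"error rates must lie in [0,1]: {self}")


@dataclass(frozen=True)
class ModelParams:
    """Read-model parameters.

    mu0
        Variant-read success probability for a reference library genotype
        (sequencing error scale; default 0.001).
    mu1
        Variant-read success probability for a mutant library genotype
        (0.5 = heterozygous mean on a diploid).
    min_coverage
        Coverage threshold λ below which an entry is missing data.
    """

    mu0: float = 0.001
    mu1: float = 0.5
    min_coverage: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.mu0 < self.mu1 <= 1.0):
            raise ValueError(f"require 0 < mu0 < mu1 <= 1, got {self}")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")


@dataclass
class LikelihoodTables:
    """Per-entry log-likelihood tables for the two genotype hypotheses.

    ``one`` (o_ij) assumes g=1 everywhere, ``zero`` (ζ_ij) assumes g=0.
    Missing entries are exactly 0 in both tables, so they contribute nothing
    to any genotype configuration's likelihood.
    """

    one: np.ndarray
    zero: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.one.shape


def _binom_mixture(r, v, logw_ref, logw_alt, mu0: float, mu1: float):
    """log{ μ0^v (1-μ0)^r e^{logw_ref} + μ1^v (1-μ1)^r e^{logw_alt} }."""
    a = xlogy(v, mu0) + xlogy(r, 1.0 - mu0) + logw_ref
    b = xlogy(v, mu1) + xlogy(r, 1.0 - mu1) + logw_alt
    return np.logaddexp(a, b)


def entry_loglik(r, v, g, rates: ErrorRates, params: ModelParams):
    """Marginal log P(r, v | g, α, β) for scalar or array-valued r, v, g.

    Returns -inf (never NaN) when the mixture is degenerate, e.g. α=1 with
    g=0 and no variant reads possible under μ1.
    """
    r = np.asarray(r, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    g = np.asarray(g)
    if np.any(r < 0) or np.any(v < 0):
        raise ValueError("read counts must be non-negative")
    c = r + v
    log_binom = gammaln(c + 1.0) - gammaln(v + 1.0) - gammaln(r + 1.0)
    with np.errstate(divide="ignore"):
        lw = np.log([1.0 - rates.alpha, rates.alpha, rates.beta, 1.0 - rates.beta])
    ll0 = _binom_mixture(r, v, lw[0], lw[1], params.mu0, params.mu1)
    ll1 = _binom_mixture(r, v, lw[2], lw[3], params.mu0, params.mu1)
    return log_binom + np.where(np.asarray(g) == 1, ll1, ll0)


def build_tables(counts, rates: ErrorRates, params: ModelParams) -> LikelihoodTables:
    """One-/zero-allele log-likelihood tables for every (cell, locus) entry.

    Entries flagged missing by ``counts.missing_mask`` are set to exactly 0.
    """
    r, v = counts.R, counts.V
    one = entry_loglik(r, v, 1, rates, params)
    zero = entry_loglik(r, v, 0, rates, params)
    miss = counts.missing_mask
    one = np.where(miss, 0.0, one)
    zero = np.where(miss, 0.0, zero)
    return LikelihoodTables(one=one, zero=zero)


def total_loglik(G: np.ndarray, tables: LikelihoodTables) -> float:
    """Σ_ij g_ij·o_ij + (1-g_ij)·ζ_ij — the data log-likelihood of genotypes G."""
    G = np.asarray(G)
    if G.shape != tables.shape:
        raise ValueError(f"genotype shape {G.shape} != table shape {tables.shape}")
    return float(np.sum(np.where(G == 1, tables.one, tables.zero)))
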