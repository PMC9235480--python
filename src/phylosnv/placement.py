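"""Vectorized scoring of all infinite-sites mutation placements.

For a fixed tree, placing the mutation of site j at node k implies the
genotype column S[k] (subtree indicator), so the site's log-likelihood is

    χ_kj = Σ_i  S[k,i]·o_ij + (1 - S[k,i])·ζ_ij,

i.e. X = S·O + (J - S)·Z for the 2N x N indicator matrix S (last row = no
mutation). Evaluated as X = S·(O - Z) + 1·colsum(Z), a single matrix product
per block of sites, which is what lets the method scale to millions of loci.
The per-site maximum over the 2N rows is the optimal ISA placement and its
row of S is the implied genotype column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import LikelihoodTables

__all__ = ["PlacementResult", "score_placements", "best_placement"]


@dataclass
class PlacementResult:
    """Optimal per-site placement on a fixed tree.

    k_star
        Length-M argmax row of the placement-score matrix (ties -> smallest
        index; index 2N-1 means "no mutation at this site").
    G
        N x M implied genotype matrix (column j = S row k_star[j]).
    per_site_loglik
        Column maxima of the score matrix; sums to the total log-likelihood
        of G.
    """

    k_star: np.ndarray
    G: np.ndarray
    per_site_loglik: np.ndarray

    @property
    def total_loglik(self) -> float:
        return float(self.per_site_loglik.sum())

    @property
    def is_snv(self) -> np.ndarray:
        """Site called as an SNV iff some node carries its mutation."""
        no_mutation_row = self.G.shape[0] * 2 - 1
        return self.k_star != no_mutation_row


def score_placements(S: np.ndarray, tables: LikelihoodTables) -> np.ndarray:
    """Full 2N x M placement-score matrix X = S·O + (J-S)·Z."""
    return _score_block(S, tables.one, tables.zero)


def _score_block(S: np.ndarray, O: np.ndarray, Z: np.ndarray) -> np.ndarray:
    return S @ (O - Z) + Z.sum(axis=0)[None, :]


def best_placement(
    S: np.ndarray,
    tables: LikelihoodTables,
    block_size: int | None = None,
) -> PlacementResult:
    """Per-site optimal placement, optionally in column blocks.

    With ``block_size`` set, peak memory is O(2N·block) instead of O(2N·M).
    Each column is the same dot products either way; scores can differ from
    the unblocked product only in the last floating-point bits (BLAS kernel
    selection depends on operand shape), which leaves the per-site argmax and
    genotypes unchanged except between placements whose scores tie to ~1e-12.
    """
    O, Z = tables.one, tables.zero
    n, m = O.shape
    if block_size is None or block_size >= m:
        X = _score_block(S, O, Z)
        k_star = np.argmax(X, axis=0)
        per_site = X[k_star, np.arange(m)]
    else:
        k_star = np.empty(m, dtype=np.int64)
        per_site = np.empty(m, dtype=np.float64)
        for lo in range(0, m, block_size):
            hi = min(lo + block_size, m)
            Xb = _score_block(S, O[:, lo:hi], Z[:, lo:hi])
            kb = np.argmax(Xb, axis=0)
            k_star[lo:hi] = kb
            per_site[lo:hi] = Xb[kb, np.arange(hi - lo)]
    G = S[k_star, :].T.astype(np.int8)
    return PlacementResult(k_star=k_star, G=G, per_site_loglik=per_site)
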