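"""Joint hill-climbing over tree topology, mutation placements and error rates.

The search maximizes the read-count log-likelihood F(R,V | G, α, β) where the
genotype matrix G is always the optimal per-site ISA placement on the current
tree. One chain:

1. Initial genotypes G0: per-entry comparison of the error-free (α=β=0)
   likelihoods of g=1 vs g=0; missing entries are 0.
2. Initial tree: neighbor joining on pairwise-complete Hamming distances
   between the rows of G0.
3. Iterate: propose either new error rates (re-estimated from the discordance
   between G0 and the current genotypes) or a random tree rearrangement
   (NNI / SPR / leaf swap); re-score all placements; accept when the new
   log-likelihood is >= the current one (strict mode) or with Metropolis
   probability min{1, exp(ΔF)} (stochastic mode).
4. Stop after ``patience`` iterations without improving the best-ever
   likelihood, or at ``max_iterations``.

Multiple chains run independently from distinct seeds; the best final
likelihood wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrices
from .likelihood import ErrorRates, ModelParams, build_tables
from .placement import best_placement
from .tree import CellTree, hamming_distances, neighbor_joining, random_move

__all__ = [
    "SearchConfig",
    "SearchState",
    "initial_genotypes",
    "propose_error_rates",
    "accept",
    "run_chain",
    "run_parallel",
]

logger = logging.getLogger(__name__)

_IMPROVE_TOL = 1e-9


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the hill-climbing search.

    ``rate_proposal_period`` K: every K-th iteration proposes new error rates,
    all others propose a tree move. ``error_denominator`` selects the
    normalization of the error-rate re-estimates: "conditional" divides the
    discordant entries by the covered entries of the matching genotype class
    (so β̂ estimates P(observed 0 | called 1)), "all_covered" divides both by
    all covered entries. ``accept_rule`` applies in stochastic mode only:
    "metropolis" is min{1, exp(ΔF)}; "literal" is the ratio of the two
    log-likelihood values themselves (kept for fidelity experiments; not a
    proper acceptance probability).
    """

    max_iterations: int = 100_000
    patience: int = 5_000
    stochastic: bool = False
    move_probs: tuple[float, float, float] = (0.5, 0.4, 0.1)
    rate_proposal_period: int = 10
    block_size: int | None = None
    n_chains: int = 1
    error_denominator: str = "conditional"
    accept_rule: str = "metropolis"
    log_every: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_iterations:
            raise ValueError("patience must be <= max_iterations")
        if not np.isclose(sum(self.move_probs), 1.0):
            raise ValueError("move probabilities must sum to 1")
        if self.error_denominator not in ("conditional", "all_covered"):
            raise ValueError(f"unknown error_denominator {self.error_denominator!r}")
        if self.accept_rule not in ("metropolis", "literal"):
            raise ValueError(f"unknown accept_rule {self.accept_rule!r}")
        if self.rate_proposal_period < 2:
            raise ValueError("rate_proposal_period must be >= 2")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class SearchState:
    """Best-ever state of one chain plus its accepted-likelihood trace."""

    iteration: int
    tree: CellTree
    rates: ErrorRates
    G: np.ndarray
    loglik: float
    G0: np.ndarray
    seed: int | None
    trace: np.ndarray = field(repr=False, default=None)
    n_iterations_run: int = 0

    @property
    def alpha(self) -> float:
        return self.rates.alpha

    @property
    def beta(self) -> float:
        return self.rates.beta


def initial_genotypes(counts: CountMatrices, params: ModelParams) -> np.ndarray:
    """Per-entry error-free genotype calls.

    g0_ij = 1 iff the one-allele likelihood beats the zero-allele likelihood
    at α=β=0 (i.e. v·log(μ1/μ0) + r·log((1-μ1)/(1-μ0)) > 0); missing entries
    and ties are 0.
    """
    tables = build_tables(counts, ErrorRates(0.0, 0.0), params)
    g0 = (tables.one > tables.zero) & ~counts.missing_mask
    return g0.astype(np.int8)


def propose_error_rates(
    G0: np.ndarray,
    Gprev: np.ndarray,
    covered: np.ndarray,
    denominator: str = "conditional",
) -> ErrorRates:
    """Re-estimate (α, β) from disagreement between G0 and the current calls.

    Entries the tree-aware calls corrected from an initial 1 to 0 measure the
    false-positive rate; initial 0s corrected to 1 (mutations the raw reads
    missed, e.g. through allelic dropout) measure the false-negative rate.
    Only entries with non-zero coverage are counted. With
    ``denominator="conditional"`` each count is normalized by the covered
    entries of its current genotype class; with "all_covered" both use all
    covered entries.
    """
    G0 = np.asarray(G0)
    Gprev = np.asarray(Gprev)
    covered = np.asarray(covered, dtype=bool)
    n_fp = int(np.sum((G0 == 1) & (Gprev == 0) & covered))
    n_fn = int(np.sum((G0 == 0) & (Gprev == 1) & covered))
    if denominator == "conditional":
        den_a = int(np.sum((Gprev == 0) & covered))
        den_b = int(np.sum((Gprev == 1) & covered))
    elif denominator == "all_covered":
        den_a = den_b = int(np.sum(covered))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if den_a == 0 and den_b == 0:
        warnings.warn("no covered entries; proposing zero error rates", stacklevel=2)
    alpha = n_fp / den_a if den_a else 0.0
    beta = n_fn / den_b if den_b else 0.0
    return ErrorRates(alpha=alpha, beta=beta)


def accept(
    loglik_new: float,
    loglik_old: float,
    stochastic: bool = False,
    rng: np.random.Generator | None = None,
    rule: str = "metropolis",
) -> bool:
    """Acceptance decision for a proposed state.

    Strict mode accepts iff the new log-likelihood is greater than or equal
    to the old one. Stochastic mode accepts improvements always and
    deteriorations with probability exp(ΔF) ("metropolis"); the "literal"
    rule uses min{1, F_new/F_old} on the raw log-likelihood values.
    """
    if not stochastic:
        return loglik_new >= loglik_old
    if rng is None:
        raise ValueError("stochastic acceptance needs an rng")
    if rule == "metropolis":
        delta = loglik_new - loglik_old
        p = 1.0 if delta >= 0 else float(np.exp(delta))
    elif rule == "literal":
        p = min(1.0, loglik_new / loglik_old) if loglik_old != 0 else 1.0
        if np.isnan(p) or p < 0:
            p = 0.0
    else:
        raise ValueError(f"unknown accept rule {rule!r}")
    return bool(rng.random() < p)


def run_chain(
    counts: CountMatrices,
    params: ModelParams,
    config: SearchConfig,
    seed: int | None = None,
) -> SearchState:
    """One hill-climbing chain; returns its best-ever state."""
    if counts.n_cells < 3:
        raise ValueError("need at least 3 cells")
    if counts.n_sites == 0:
        raise ValueError("no candidate loci left after filtering")
    rng = np.random.default_rng(seed)
    covered = counts.coverage != 0

    G0 = initial_genotypes(counts, params)
    D = hamming_distances(G0, counts.missing_mask)
    tree = neighbor_joining(D, counts.cell_names)

    rates = ErrorRates(0.0, 0.0)
    tables = build_tables(counts, rates, params)
    S = tree.subtree_matrix()
    placed = best_placement(S, tables, config.block_size)
    G, loglik = placed.G, placed.total_loglik

    best = SearchState(
        iteration=1, tree=tree.copy(), rates=rates, G=G.copy(),
        loglik=loglik, G0=G0, seed=seed,
    )
    trace = [loglik]
    no_improve = 0
    t = 1
    while t < config.max_iterations and no_improve < config.patience:
        t += 1
        if t % config.rate_proposal_period == 0:
            new_rates = propose_error_rates(G0, G, covered, config.error_denominator)
            new_tree, new_S = tree, S
            new_tables = build_tables(counts, new_rates, params)
            move = "rates"
        else:
            new_tree, move, _ = random_move(tree, rng, config.move_probs)
            new_S = new_tree.subtree_matrix()
            new_rates, new_tables = rates, tables
        placed = best_placement(new_S, new_tables, config.block_size)
        accepted = accept(
            placed.total_loglik, loglik, config.stochastic, rng, config.accept_rule
        )
        if accepted:
            tree, S, rates, tables = new_tree, new_S, new_rates, new_tables
            G, loglik = placed.G, placed.total_loglik
        if loglik > best.loglik + _IMPROVE_TOL:
            best = SearchState(
                iteration=t, tree=tree.copy(), rates=rates, G=G.copy(),
                loglik=loglik, G0=G0, seed=seed,
            )
            no_improve = 0
        else:
            no_improve += 1
        trace.append(loglik)
        if config.log_every and t % config.log_every == 0:
            logger.info(
                "iter=%d F=%.4f alpha=%.4g beta=%.4g move=%s accepted=%s",
                t, loglik, rates.alpha, rates.beta, move, accepted,
            )
    best.trace = np.asarray(trace)
    best.n_iterations_run = t
    return best


def run_parallel(
    counts: CountMatrices,
    params: ModelParams,
    config: SearchConfig,
    seed: int | None = None,
) -> tuple[SearchState, list[SearchState]]:
    """Run ``config.n_chains`` independent chains; return (best state, all states).

    Chain seeds are spawned deterministically from ``seed``, chains share no
    mutable state, and ties in the final likelihood go to the lowest chain
    index, so the result does not depend on execution order.
    """
    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_chains)]
    states = [run_chain(counts, params, config, s) for s in chain_seeds]
    best_idx = int(np.argmax([s.loglik for s in states]))
    return states[best_idx], states
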