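"""Model/Results facade for phylogeny-aware single-cell SNV calling.

``PhyloSNV`` holds the observed count matrices and the read-model parameters;
``fit`` runs the joint hill-climbing search (tree topology, per-site
infinite-sites mutation placements, global error rates) and returns a
``PhyloSNVResults`` carrying the maximum-likelihood genotypes, tree and error
rates together with the search diagnostics.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrices, Locus, parse_mpileup, write_outputs
from .likelihood import ModelParams, build_tables, total_loglik
from .search import SearchConfig, SearchState, initial_genotypes, run_parallel
from .tree import CellTree

__all__ = ["PhyloSNV", "PhyloSNVResults"]


class PhyloSNV:
    """Phylogeny-aware SNV calling model for single-cell read counts.

    Parameters
    ----------
    counts
        Paired reference/variant count matrices (cells x loci).
    mu0, mu1
        Variant-read success probabilities for reference and mutant library
        genotypes (sequencing-error scale and heterozygous mean).
    """

    def __init__(self, counts: CountMatrices, mu0: float = 0.001, mu1: float = 0.5):
        self.counts = counts
        self.params = ModelParams(mu0=mu0, mu1=mu1, min_coverage=counts.min_coverage)

    @classmethod
    def from_mpileup(
        cls,
        source,
        cell_names: Sequence[str],
        min_coverage: int = 1,
        **kwargs,
    ) -> "PhyloSNV":
        """Build the model directly from mpileup text."""
        counts = parse_mpileup(source, cell_names, min_coverage=min_coverage)
        return cls(counts, **kwargs)

    @classmethod
    def from_arrays(
        cls,
        R: np.ndarray,
        V: np.ndarray,
        loci: Sequence[Locus] | None = None,
        cell_names: Sequence[str] | None = None,
        min_coverage: int = 1,
        **kwargs,
    ) -> "PhyloSNV":
        """Build the model from raw reference/variant count arrays."""
        R = np.asarray(R)
        n, m = R.shape
        if loci is None:
            loci = [Locus("chr1", j + 1, "A", "C") for j in range(m)]
        if cell_names is None:
            cell_names = [f"cell{i}" for i in range(n)]
        counts = CountMatrices(
            R=R, V=np.asarray(V), loci=list(loci), cell_names=list(cell_names),
            min_coverage=min_coverage,
        )
        return cls(counts, **kwargs)

    def initial_genotypes(self) -> np.ndarray:
        """Error-free per-entry genotype calls used to seed the search."""
        return initial_genotypes(self.counts, self.params)

    def fit(
        self,
        n_chains: int = 1,
        seed: int | None = None,
        max_iterations: int = 100_000,
        patience: int = 5_000,
        stochastic: bool = False,
        **config_kwargs,
    ) -> "PhyloSNVResults":
        """Run the hill-climbing search and return the best state across chains."""
        config = SearchConfig(
            n_chains=n_chains,
            max_iterations=max_iterations,
            patience=patience,
            stochastic=stochastic,
            **config_kwargs,
        )
        best, states = run_parallel(self.counts, self.params, config, seed=seed)
        return PhyloSNVResults(self, config, best, states, seed)


class PhyloSNVResults:
    """Fitted genotypes, tree and error rates with search diagnostics."""

    def __init__(
        self,
        model: PhyloSNV,
        config: SearchConfig,
        best: SearchState,
        states: list[SearchState],
        seed: int | None,
    ):
        self.model = model
        self.config = config
        self.state = best
        self.chain_states = states
        self.seed = seed

    # convenient scalar views ------------------------------------------------
    @property
    def genotypes(self) -> np.ndarray:
        return self.state.G

    @property
    def tree(self) -> CellTree:
        return self.state.tree

    @property
    def alpha(self) -> float:
        return self.state.rates.alpha

    @property
    def beta(self) -> float:
        return self.state.rates.beta

    @property
    def loglik(self) -> float:
        return self.state.loglik

    @property
    def trace(self) -> np.ndarray:
        return self.state.trace

    @property
    def n_iter(self) -> int:
        return self.state.n_iterations_run

    @property
    def snv_sites(self) -> np.ndarray:
        """Indices of loci called as SNVs (any cell mutated)."""
        return np.flatnonzero((self.genotypes == 1).any(axis=0))

    def recomputed_loglik(self) -> float:
        """Data log-likelihood of the fitted genotypes, rebuilt from scratch."""
        tables = build_tables(self.model.counts, self.state.rates, self.model.params)
        return total_loglik(self.genotypes, tables)

    def genotype_frame(self) -> pd.DataFrame:
        counts = self.model.counts
        return pd.DataFrame(
            self.genotypes,
            index=counts.cell_names,
            columns=[f"{l.chrom}:{l.pos}" for l in counts.loci],
        )

    def tree_newick(self) -> str:
        return self.tree.to_newick()

    def save(self, outdir) -> dict:
        """Write VCF + Newick + JSON report to a directory."""
        return write_outputs(self, self.model.counts, outdir)

    def plot_trace(self, ax=None):
        """Accepted log-likelihood trace of the best chain."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.trace) + 1), self.trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("log-likelihood")
        return ax

    def summary(self) -> str:
        counts = self.model.counts
        lines = [
            "Phylogeny-aware SNV calling results",
            "=" * 44,
            f"{'cells':<28}{counts.n_cells:>16}",
            f"{'candidate loci':<28}{counts.n_sites:>16}",
            f"{'chains':<28}{self.config.n_chains:>16}",
            f"{'iterations (best chain)':<28}{self.n_iter:>16}",
            f"{'log-likelihood':<28}{self.loglik:>16.4f}",
            f"{'false-positive rate alpha':<28}{self.alpha:>16.6f}",
            f"{'false-negative rate beta':<28}{self.beta:>16.6f}",
            f"{'SNV sites called':<28}{len(self.snv_sites):>16}",
            f"{'mutant genotype entries':<28}{int((self.genotypes == 1).sum()):>16}",
            "=" * 44,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<PhyloSNVResults loglik={self.loglik:.3f} alpha={self.alpha:.4f} "
            f"beta={self.beta:.4f} snv_sites={len(self.snv_sites)}>"
        )
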