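"""Scoring inferred genotypes against simulation truth and benchmark sweeps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import ModelParams
from .search import SearchConfig, run_parallel
from .simulate import SimConfig, simulate

__all__ = [
    "CallMetrics",
    "score_calls",
    "score_sites",
    "beta_vs_ado_experiment",
    "BetaAdoResult",
]


@dataclass(frozen=True)
class CallMetrics:
    """Entry-level confusion counts and derived precision/recall/F1."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


def score_calls(
    G_hat: np.ndarray,
    G_true: np.ndarray,
    missing_mask: np.ndarray | None = None,
    exclude_missing: bool = True,
) -> CallMetrics:
    """Entry-level (cell x site) confusion of calls against truth.

    Missing observations are excluded by default: calls there are imputed by
    the tree rather than observed.
    """
    G_hat = np.asarray(G_hat)
    G_true = np.asarray(G_true)
    if G_hat.shape != G_true.shape:
        raise ValueError("shape mismatch between calls and truth")
    use = np.ones(G_hat.shape, dtype=bool)
    if exclude_missing and missing_mask is not None:
        use = ~np.asarray(missing_mask, dtype=bool)
    h, t = G_hat[use] == 1, G_true[use] == 1
    return CallMetrics(
        tp=int(np.sum(h & t)),
        fp=int(np.sum(h & ~t)),
        fn=int(np.sum(~h & t)),
        tn=int(np.sum(~h & ~t)),
    )


def score_sites(G_hat: np.ndarray, G_true: np.ndarray) -> CallMetrics:
    """Site-level confusion: a site is an SNV iff any cell carries the mutation."""
    h = (np.asarray(G_hat) == 1).any(axis=0)
    t = (np.asarray(G_true) == 1).any(axis=0)
    return CallMetrics(
        tp=int(np.sum(h & t)),
        fp=int(np.sum(h & ~t)),
        fn=int(np.sum(~h & t)),
        tn=int(np.sum(~h & ~t)),
    )


@dataclass
class BetaAdoResult:
    """Regression of estimated false-negative rates on true dropout rates."""

    slope: float
    intercept: float
    pearson_r: float
    records: pd.DataFrame

    def __repr__(self) -> str:
        return (
            f"<BetaAdoResult slope={self.slope:.3f} intercept={self.intercept:.3f} "
            f"r={self.pearson_r:.3f} n={len(self.records)}>"
        )


def beta_vs_ado_experiment(
    ado_grid: Sequence[float],
    replicates: int,
    sim_base: SimConfig | None = None,
    search_config: SearchConfig | None = None,
    params: ModelParams | None = None,
    seed: int | None = None,
) -> BetaAdoResult:
    """Dropout-recovery sweep: simulate across an ADO grid, fit, regress β̂ on μ.

    Since dropout converts half of the selected mutant entries to reference
    library genotypes (the other half become homozygous and still read as
    mutant), the model's false-negative rate should track μ/2: slope ≈ 0.5
    with a strong linear correlation.
    """
    if not ado_grid:
        raise ValueError("ado grid must be non-empty")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    sim_base = sim_base or SimConfig()
    search_config = search_config or SearchConfig()
    params = params or ModelParams()
    root = np.random.SeedSequence(seed)
    rows = []
    for ado in ado_grid:
        for rep, ss in enumerate(root.spawn(replicates)):
            run_seed = int(ss.generate_state(1)[0] % (2**31))
            cfg = replace(sim_base, ado_rate=float(ado), seed=run_seed)
            try:
                counts, truth = simulate(cfg)
                state, _ = run_parallel(counts, params, search_config, seed=run_seed)
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"run (ado={ado}, rep={rep}) failed: {exc}", stacklevel=2)
                continue
            rows.append(
                {"ado": float(ado), "replicate": rep, "beta_hat": state.beta,
                 "alpha_hat": state.alpha, "loglik": state.loglik}
            )
    records = pd.DataFrame(rows)
    if records["ado"].nunique() > 1:
        reg = stats.linregress(records["ado"], records["beta_hat"])
        slope, intercept, r = reg.slope, reg.intercept, reg.rvalue
    else:  # degenerate grid: no regression possible
        slope, intercept, r = np.nan, float(records["beta_hat"].mean()), np.nan
    return BetaAdoResult(
        slope=float(slope), intercept=float(intercept), pearson_r=float(r),
        records=records,
    )
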