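"""Synthetic single-cell read-count datasets with known ground truth.

The generator emulates the benchmark conditions used to stress phylogeny-aware
single-cell SNV callers: a uniform random cell tree, one infinite-sites
mutation per candidate locus placed on a uniform random node, and the
characteristic single-cell artifacts layered on top —

* allelic dropout (rate μ): a μ fraction of mutated (cell, site) entries is
  selected; half become reference in the library (the mutant allele dropped),
  half become homozygous mutant (the reference allele dropped). The model's
  false-negative rate β therefore corresponds to ≈ μ/2.
* false positives: reference entries switch to a mutant library state at a
  small per-entry rate.
* copy-number inflation: a fraction of mutated loci receives c extra
  wild-type copies with P(c) ∝ 1/2^c (c = 1..8), pushing the expected variant
  allele fraction of heterozygous entries down to 1/(2+c).
* ISA violations: a fraction of sites either recurs on a second, non-nested
  branch or loses the mutation again in a sub-clade.

Read counts: per-entry coverage is negative binomial, parametrized by its
mean and its index of dispersion (variance-to-mean ratio; amplified
single-cell libraries are overdispersed, ratio > 1). Variant reads are
binomial with success probability μ0 (reference library state), 1/(2+c)
(heterozygous) or 1-μ0 (homozygous mutant). Entries may additionally be
dropped to zero coverage at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import CountMatrices, Locus
from .tree import CellTree

__all__ = ["SimConfig", "SimTruth", "simulate", "write_mpileup", "write_truth"]

_MAX_EXTRA_COPIES = 8


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the benchmark conditions.

    ``coverage_dispersion`` is the index of dispersion (variance/mean) of the
    negative-binomial coverage, > 1. ``ado_unit`` chooses whether dropout hits
    a fraction of mutated (cell, site) entries ("entry", default) or whole
    mutation sites ("site").
    """

    n_cells: int = 16
    n_sites: int = 1000
    ado_rate: float = 0.0
    fp_rate: float = 0.0
    coverage_mean: float = 25.0
    coverage_dispersion: float = 2.0
    missing_rate: float = 0.0
    cn_rate: float = 0.0
    isa_violation_rate: float = 0.0
    mu0: float = 0.001
    seed: int | None = None
    ado_unit: str = "entry"

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("need at least 3 cells")
        for name in ("ado_rate", "fp_rate", "missing_rate", "cn_rate", "isa_violation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage mean must be positive")
        if self.coverage_dispersion <= 1.0:
            raise ValueError("coverage dispersion (variance/mean) must exceed 1")
        if self.ado_unit not in ("entry", "site"):
            raise ValueError("ado_unit must be 'entry' or 'site'")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    tree: CellTree
    genotypes: np.ndarray  # N x M true binary genotypes
    mutation_node: np.ndarray  # length M, node index carrying each site's mutation
    ado_ref_entries: np.ndarray = field(default=None)  # (k,2) dropout->reference
    ado_hom_entries: np.ndarray = field(default=None)  # (k,2) dropout->homozygous
    cn_sites: dict[int, int] = field(default_factory=dict)  # site -> extra copies c
    isa_recurrent_sites: list[int] = field(default_factory=list)
    isa_lost_sites: list[int] = field(default_factory=list)


def _pick_extra_copies(rng: np.random.Generator, size: int) -> np.ndarray:
    c = np.arange(1, _MAX_EXTRA_COPIES + 1)
    p = 0.5**c
    return rng.choice(c, size=size, p=p / p.sum())


def simulate(config: SimConfig) -> tuple[CountMatrices, SimTruth]:
    """Generate one dataset; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_cells, config.n_sites
    tree = CellTree.random_topology(n, rng)
    S = tree.subtree_matrix().astype(np.int8)

    # one mutation per site on a uniform random node (never the "none" row,
    # so every site has at least one mutated cell)
    mut_node = rng.integers(0, tree.n_nodes, size=m)
    G_true = S[mut_node, :].T.copy()  # N x M

    truth = SimTruth(tree=tree, genotypes=G_true, mutation_node=mut_node)

    # ISA violations: half recurrence on a non-nested branch, half loss in a
    # sub-clade of the mutated subtree
    n_viol = int(round(config.isa_violation_rate * m))
    if n_viol:
        viol_sites = rng.choice(m, size=n_viol, replace=False)
        half = n_viol // 2
        for j in viol_sites[:half]:
            leaves_j = np.flatnonzero(G_true[:, int(j)])
            disjoint = [
                k for k in range(tree.n_nodes)
                if not (S[k] & G_true[:, int(j)]).any() and S[k].any()
            ]
            if not disjoint:
                continue
            k2 = int(rng.choice(disjoint))
            G_true[:, int(j)] |= S[k2]
            truth.isa_recurrent_sites.append(int(j))
        for j in viol_sites[half:]:
            node = int(mut_node[int(j)])
            if tree.is_leaf(node):
                continue  # a single-cell mutation has no proper sub-clade to lose
            sub = int(tree.children[node, rng.integers(0, 2)])
            G_true[:, int(j)] &= 1 - S[sub]
            truth.isa_lost_sites.append(int(j))

    # library states: 0 reference, 1 heterozygous mutant, 2 homozygous mutant
    state = G_true.astype(np.int8).copy()

    mut_i, mut_j = np.nonzero(G_true == 1)
    if config.ado_rate > 0 and mut_i.size:
        if config.ado_unit == "entry":
            n_ado = int(np.floor(config.ado_rate * mut_i.size))
            pick = rng.choice(mut_i.size, size=n_ado, replace=False)
            half = n_ado // 2
            ref_sel, hom_sel = pick[:half], pick[half:]
            state[mut_i[ref_sel], mut_j[ref_sel]] = 0
            state[mut_i[hom_sel], mut_j[hom_sel]] = 2
            truth.ado_ref_entries = np.column_stack([mut_i[ref_sel], mut_j[ref_sel]])
            truth.ado_hom_entries = np.column_stack([mut_i[hom_sel], mut_j[hom_sel]])
        else:  # whole mutation sites drop together
            n_ado = int(np.floor(config.ado_rate * m))
            sites = rng.choice(m, size=n_ado, replace=False)
            half = n_ado // 2
            for j in sites[:half]:
                state[G_true[:, int(j)] == 1, int(j)] = 0
            for j in sites[half:]:
                state[G_true[:, int(j)] == 1, int(j)] = 2
            ref_mask = np.zeros_like(state, dtype=bool)
            hom_mask = np.zeros_like(state, dtype=bool)
            for j in sites[:half]:
                ref_mask[G_true[:, int(j)] == 1, int(j)] = True
            for j in sites[half:]:
                hom_mask[G_true[:, int(j)] == 1, int(j)] = True
            truth.ado_ref_entries = np.argwhere(ref_mask)
            truth.ado_hom_entries = np.argwhere(hom_mask)

    if config.fp_rate > 0:
        flip = (state == 0) & (rng.random(state.shape) < config.fp_rate)
        state[flip] = 1

    # copy-number inflation at a fraction of mutated loci
    vaf = np.full(m, 0.5)
    if config.cn_rate > 0:
        mutated_sites = np.flatnonzero((G_true == 1).any(axis=0))
        n_cn = int(round(config.cn_rate * mutated_sites.size))
        if n_cn:
            cn_sites = rng.choice(mutated_sites, size=n_cn, replace=False)
            extra = _pick_extra_copies(rng, n_cn)
            vaf[cn_sites] = 1.0 / (2.0 + extra)
            truth.cn_sites = {int(j): int(c) for j, c in zip(cn_sites, extra)}

    # read counts: NB with mean m and variance ratio d -> size m/(d-1), p 1/d
    ratio = config.coverage_dispersion
    nb_size = config.coverage_mean / (ratio - 1.0)
    coverage = rng.negative_binomial(nb_size, 1.0 / ratio, size=(n, m))
    if config.missing_rate > 0:
        coverage[rng.random((n, m)) < config.missing_rate] = 0
    p_var = np.where(state == 0, config.mu0,
                     np.where(state == 1, vaf[None, :], 1.0 - config.mu0))
    V = rng.binomial(coverage, p_var)
    R = coverage - V

    loci = [Locus("chr1", j + 1, "A", "C") for j in range(m)]
    names = [f"cell{i}" for i in range(n)]
    counts = CountMatrices(R=R, V=V, loci=loci, cell_names=names, min_coverage=1)
    tree.names = names
    return counts, truth


def write_mpileup(counts: CountMatrices, path) -> None:
    """Serialize counts as minimal valid mpileup (refs as '.', alts explicit).

    Round-trips through the mpileup parser: reference reads come first as
    '.', then variant reads as the alt base, with constant qualities.
    ``path`` may be a filesystem path or an open text stream.
    """
    import contextlib

    cm = (
        contextlib.nullcontext(path)
        if hasattr(path, "write")
        else open(path, "w")
    )
    with cm as f:
        for j, loc in enumerate(counts.loci):
            fields = [loc.chrom, str(loc.pos), loc.ref]
            for i in range(counts.n_cells):
                r, v = int(counts.R[i, j]), int(counts.V[i, j])
                cov = r + v
                if cov == 0:
                    fields += ["0", "*", "*"]
                else:
                    fields += [str(cov), "." * r + loc.alt * v, "I" * cov]
            f.write("\t".join(fields) + "\n")


def write_truth(truth: SimTruth, counts: CountMatrices, outdir) -> None:
    """Write the ground truth as plain text: genotypes TSV + Newick tree + site table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "true_genotypes.tsv", "w") as f:
        f.write("cell\t" + "\t".join(f"{l.chrom}:{l.pos}" for l in counts.loci) + "\n")
        for i, name in enumerate(counts.cell_names):
            f.write(name + "\t" + "\t".join(map(str, truth.genotypes[i])) + "\n")
    (outdir / "true_tree.nwk").write_text(truth.tree.to_newick() + "\n")
    with open(outdir / "site_info.tsv", "w") as f:
        f.write("site\tmutation_node\textra_copies\tisa_violation\n")
        for j in range(counts.n_sites):
            viol = (
                "recurrent" if j in truth.isa_recurrent_sites
                else "lost" if j in truth.isa_lost_sites
                else "none"
            )
            f.write(
                f"{j}\t{int(truth.mutation_node[j])}\t{truth.cn_sites.get(j, 0)}\t{viol}\n"
            )
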