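# Methods

## Model

`phylosnv` calls single-nucleotide variants from single-cell DNA sequencing
read counts by maximum likelihood over four coupled unknowns: a rooted binary
topology T on the N cells, a per-site mutation placement under the
infinite-sites assumption (ISA), the implied binary genotype matrix
G ∈ {0,1}^(N×M), and two global error rates (α, β).

Per (cell, site) entry the data are the reference/variant read counts
(r, v). Two error layers connect them to the true genotype g:

1. the *library* genotype ψ differs from g with probability α (false
   positive, P(ψ=1|g=0)) or β (false negative, P(ψ=0|g=1)) — these absorb
   amplification artifacts such as allelic dropout;
2. given ψ, the variant count is binomial, v ~ Bin(r+v, μ_ψ).

ψ is summed out analytically, giving a closed-form entry log-likelihood that
is a two-component binomial mixture in log space. Entries with coverage below
λ are missing and contribute exactly 0, i.e. they are likelihood-neutral and
their genotypes are imposed purely by the tree placement.

Under the ISA, the genotype column reachable at a site is exactly one row of
the (2N)×N subtree-indicator matrix S of the current tree (row k = leaves
below node k; an appended all-zero row encodes "no mutation"). Writing O and
Z for the N×M tables of entry log-likelihoods under g=1 and g=0, the scores
of all 2N placements at all M sites are the single product
X = S·O + (J−S)·Z, evaluated here as S·(O−Z) + 1·colsum(Z) (one GEMM per
block of sites). This vectorization is what makes the per-iteration cost
linear in M and lets the tool handle very large candidate-locus panels.

### Assumptions and their consequences

- **ISA** (each site mutates once, no back-mutation): a site's carriers form
  one clade. Recurrent or lost mutations are representable only approximately
  by the closest single clade; the simulator can generate such violations to
  quantify the degradation.
- **Binary genotypes**: heterozygous and homozygous-alternate states are not
  distinguished; μ₁ = 0.5 encodes the heterozygous expectation, and
  homozygous-alternate entries (e.g. produced by dropout of the reference
  allele) simply look like very confident mutant entries.
- **Global error rates**: α and β are shared by all cells and sites.
- **Independence across sites** given genotypes.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| μ₀ | variant-read probability, reference library genotype | 0.001 | Illumina-scale per-base error |
| μ₁ | variant-read probability, mutant library genotype | 0.5 | heterozygous mean on a diploid |
| λ | missing-data coverage threshold (reads) | 1 | only zero-coverage entries are unobserved |
| α, β | genotype error rates | estimated (init 0, 0) | re-estimated during the search |
| move mixture | NNI / SPR / leaf-swap probabilities | 0.5 / 0.4 / 0.1 | cheap local moves dominate; SPR escapes larger basins; occasional leaf swaps fix misplaced single cells |
| K | error-rate proposal period (iterations) | 10 | rates change slowly; re-estimating every iteration wastes table rebuilds |
| patience | iterations without best-likelihood improvement before stopping | 5000 | conservative default for real panels |
| max_iterations | hard iteration cap | 100000 | matches long production runs |

## Search

- **Initial genotypes G⁰**: per-entry comparison of the g=1 vs g=0
  log-likelihoods at α=β=0, which reduces to
  v·log(μ₁/μ₀) + r·log((1−μ₁)/(1−μ₀)) > 0; ties and missing entries are 0.
  G⁰ is frozen and later serves as the reference point for error-rate
  re-estimation.
- **Initial tree**: neighbor joining (scikit-bio) on pairwise-complete
  normalized Hamming distances between rows of G⁰ (loci missing in either
  cell are excluded from that pair's distance; cells sharing no observed loci
  get distance 0). NJ returns an unrooted tree; it is rooted deterministically
  on the edge to the first child of its trifurcation. Root placement only
  determines which node carries a clonal (all-cells) placement; every rooting
  exposes the same clade set plus the all-ones row.
- **Proposals**: every K-th iteration re-estimates (α, β); all other
  iterations draw one tree rearrangement. New rates require rebuilding O and
  Z; new trees require rebuilding S; either way all placements are re-scored
  and G is reset to the per-site optima, so the accepted likelihood is always
  the exact likelihood of the current state (no incremental drift — an
  invariant the tests recompute from scratch).
- **Error-rate re-estimation**: α̂ is the fraction of covered entries called
  0 now but 1 in G⁰ among covered entries currently called 0; β̂ the fraction
  called 1 now but 0 in G⁰ among covered entries currently called 1. In other
  words the current tree-aware calls are treated as the truth proxy and the
  initial raw calls as the observation, estimating P(observed 1 | true 0) and
  P(observed 0 | true 1) directly. Normalizing instead by *all* covered
  entries (available as `error_denominator="all_covered"`) estimates flip
  counts rather than flip probabilities; it produces the same near-perfect
  correlation with the dropout rate but a much smaller slope (scaled by the
  mean fraction of entries mutated), so the class-conditional form is the
  default.
- **Acceptance**: strict mode accepts iff the new log-likelihood is ≥ the
  current one (so equal-likelihood moves still allow lateral drift across
  plateaus). Stochastic mode uses min{1, exp(ΔF)}; a `literal` variant that
  takes the raw ratio of the two log-likelihood values is kept behind a flag
  for fidelity experiments only — a ratio of two negative log-likelihoods is
  not a proper acceptance probability (it *penalizes* improvements) and is
  never the default.
- **Termination**: `patience` iterations without improving the best-ever
  likelihood (tolerance 1e-9), or `max_iterations`. With patience 0 the
  result is the iteration-1 state (NJ tree + first placement).
- **Chains**: independent restarts with seeds spawned deterministically from
  the root seed; the highest final likelihood wins, ties to the lowest chain
  index. Everything stochastic (move choice, edges, leaves, acceptance draws)
  flows from one generator per chain, so a fixed seed is bit-reproducible.

## Numerical choices

- Entry likelihoods use `xlogy`/`logaddexp`, so boundary rates (α, β ∈ {0,1})
  and extreme counts give −inf, never NaN, and high coverage cannot
  underflow.
- The log C(c, v) binomial coefficients are constant in g; they are kept
  inside O and Z (identical in both), so reported likelihoods are absolute
  while placement argmaxes are unaffected.
- Per-site argmax ties break to the smallest node index (common at
  all-missing sites, where every placement scores 0; such sites surface as
  calls on cell 0's leaf and are best removed up front with the candidate
  pre-filter).
- `block_size` evaluates X in column blocks, capping peak memory at
  O(N·block) while scanning arbitrarily many loci. Blocked and unblocked
  scores agree to the last few floating-point bits (BLAS kernels vary with
  operand shape); argmaxes can differ only between placements tied at that
  resolution.
- Internal node indices are reassigned in post-order after every move; leaf
  indices are permanently bound to cells, so genotype columns are comparable
  across topologies.

## Simulator

The bundled generator produces read counts with known ground truth: a uniform
random rooted binary topology (sequential uniform edge attachment), one
mutation per site on a uniform random node, then

- **allelic dropout** (rate μ): a ⌊μ·#mutant entries⌋ subset of mutated
  (cell, site) entries is selected; half become reference in the library,
  half homozygous mutant (counts differ by at most one). A site-level variant
  (whole mutations drop together) is available via `ado_unit="site"`.
  Because only the reference-converted half hides the mutation, the model's
  β corresponds to ≈ μ/2.
- **false positives**: genotype-0 entries switch to a mutant library state
  independently at `fp_rate`.
- **copy-number inflation**: a `cn_rate` fraction of mutated loci gains c
  extra wild-type copies, c ∈ {1..8} with P(c) ∝ 1/2^c (truncated and
  renormalized), lowering the heterozygous variant-allele fraction to
  1/(2+c).
- **ISA violations**: half of the selected sites recur on a second node
  disjoint from the original clade; half lose the mutation in a random child
  sub-clade of the mutated node (leaf placements, which have no proper
  sub-clade, are skipped).
- **coverage**: negative binomial with mean 25 and index of dispersion
  (variance/mean) 2 by default — overdispersed relative to Poisson, as
  amplified single-cell libraries are. The index-of-dispersion
  parametrization keeps the low-coverage tail realistic but bounded; extreme
  amplification-bias tails can be emulated by raising the ratio. Entries are
  additionally zeroed at `missing_rate`.

What the generator does **not** emulate: per-cell or per-site error-rate
variation, doublets, chimeric reads, mappability artifacts, germline
contamination, or read-level effects (qualities, strand bias). Tests passing
on these simulations therefore demonstrate the estimator's correctness and
its robustness to the modeled error processes, not performance on any
particular real platform.

## Benchmark problem sizes

The dropout-recovery experiment (`scripts/acceptance.py` and the matching
test) uses the full benchmark grid — eight dropout rates {0, …, 0.35} × ten
replicates, 16 cells × 1000 sites at coverage mean 25 — with chains capped at
2000 iterations / patience 300; on problems of this size the search likelihood
plateaus within a few hundred iterations (doubling both budgets changes the
regression in the third decimal). The recovered slope of β̂ on μ settles
around 0.36 rather than the idealized 0.5: dropouts in singleton clades (and
at clade edges the placement can trim) leave no tree signal to correct, so
they are invisible to β̂. The Pearson correlation is ≈ 0.99. Error-free
recovery runs use coverage mean 40, where the probability that a singleton
mutation is unidentifiable from its reads is ~3e-6 per entry; accuracy-trend
sweeps use 5 replicates per setting with 1000 (dropout sweep) or 10⁴ (cell
sweep, at dropout 0.2) sites.

## Limitations

- Finite-sites processes (recurrent/back mutation) are approximated by the
  nearest single clade; heavy ISA violation degrades tree quality more than
  call quality.
- β̂ measures *correctable* false negatives: dropout concentrated in
  singleton clades is underestimated by construction.
- No branch lengths or time calibration are inferred; the topology is a
  means to regularize genotypes.
- Candidate-locus selection is a simple pooled-evidence threshold
  (`prefilter_candidates`), not a statistical test; very noisy panels may
  need stricter upstream filtering.
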