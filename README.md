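# phylosnv

Phylogeny-aware maximum-likelihood SNV calling from single-cell DNA
sequencing read counts.

## The problem

Single-cell DNA sequencing (scDNAseq) requires whole-genome amplification,
which corrupts genotype signal with allelic dropout (a heterozygous site
loses one allele — false negatives), spurious amplification errors (false
positives) and wildly uneven coverage (missing data). Calling
single-nucleotide variants cell by cell is therefore noisy; but the cells
share an evolutionary history, and a mutation that is real should sit on a
*clade* of that history. `phylosnv` exploits this: it jointly infers a rooted
binary tree over the cells, the placement of each candidate site's mutation
on that tree under the infinite-sites assumption (ISA), the implied binary
genotype matrix, and global false-positive/false-negative error rates — all
by maximizing a single read-count likelihood. The likelihood of *every*
possible placement at *every* site is evaluated with one matrix product, so
the method scales to very large numbers of candidate loci.

## The model

Inputs are reference/variant read-count matrices R, V ∈ ℕ^(N×M) over N cells
and M candidate loci (parsed from samtools-style mpileup or given directly).
Entries with coverage c_ij = r_ij + v_ij below λ (default 1) are missing.

- **Genotype error model.** True genotype g ∈ {0,1}, library genotype
  ψ ∈ {0,1}: P(ψ=1|g=0) = α (false positive), P(ψ=0|g=1) = β (false
  negative).
- **Read-count model.** v_ij | ψ ~ Binomial(c_ij, μ_ψ) with μ₀ = 0.001
  (sequencing error) and μ₁ = 0.5 (heterozygous mean).
- **Marginal entry log-likelihood.** Summing out ψ,

      log P(r,v|g) = log C(c,v)
                   + (1−g)·log{ μ₀^v(1−μ₀)^r(1−α) + μ₁^v(1−μ₁)^r·α }
                   +   g ·log{ μ₀^v(1−μ₀)^r·β    + μ₁^v(1−μ₁)^r(1−β) }.

- **Tree model.** Under the ISA each site mutates at most once; placing site
  j's mutation at node k implies the genotype column S_k, row k of the
  2N×N subtree-indicator matrix S (last row all zeros = no mutation). With
  one-allele and zero-allele log-likelihood tables O, Z ∈ ℝ^(N×M)
  (entry log-likelihoods at g=1 and g=0, missing entries = 0), the scores of
  all placements at all sites are

      X = S·O + (J − S)·Z        (J = all-ones),

  and the per-site column maxima of X give the optimal placements, genotypes
  and the data log-likelihood.
- **Search.** Hill climbing: initial genotypes from the error-free per-entry
  rule, initial tree by neighbor joining on pairwise-complete Hamming
  distances, then iterated proposals — NNI / SPR / leaf-swap tree moves and
  periodic error-rate re-estimates from the discordance between the initial
  and current genotype matrices — accepted when the log-likelihood does not
  decrease (or by a Metropolis rule in stochastic mode). Multiple independent
  chains, best likelihood wins.

## Worked example

```python
from phylosnv import PhyloSNV, SimConfig, simulate
from phylosnv.evaluate import score_calls

counts, truth = simulate(SimConfig(n_cells=8, n_sites=500, ado_rate=0.2,
                                   coverage_mean=25, seed=7))
model = PhyloSNV(counts)                      # or PhyloSNV.from_mpileup(...)
res = model.fit(seed=1, max_iterations=2000, patience=300)
print(res.summary())
metrics = score_calls(res.genotypes, truth.genotypes, counts.missing_mask)
print(f"entry-level F1 vs truth: {metrics.f1:.4f}")
print(f"estimated beta: {res.beta:.4f}")
res.save("out/")                              # VCF + Newick + JSON report
```

prints

```
Phylogeny-aware SNV calling results
============================================
cells                                      8
candidate loci                           500
chains                                     1
iterations (best chain)                  380
log-likelihood                    -5235.6715
false-positive rate alpha           0.000361
false-negative rate beta            0.060310
SNV sites called                         472
mutant genotype entries                 1227
============================================
entry-level F1 vs truth: 0.9781
estimated beta: 0.0603
```

At a dropout rate of 0.2 the generator converts half of the affected mutant
entries to reference (the other half become homozygous and still read as
mutant), so the model's false-negative rate β tracks roughly half the dropout
rate; the estimate 0.06 reflects that the tree can only "see" dropouts it can
correct (singleton clades cannot be rescued). Despite 20% dropout, the
tree-aware calls reach F1 ≈ 0.98 against the generating truth.

The same workflow is available from the shell:

```bash
phylosnv simulate --cells 16 --sites 1000 --ado 0.2 --seed 7 --out sim/
phylosnv run --mpileup sim/reads.mpileup --names sim/cell_names.txt \
             --out fit/ --max-iters 2000 --patience 300 --seed 1
phylosnv evaluate --calls fit_calls.tsv --truth sim/true_genotypes.tsv
```

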