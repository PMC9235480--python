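"""Count-matrix input/output.

The caller consumes per-cell reference/variant read counts at candidate loci.
Counts come either from samtools-style mpileup text (one line per locus,
three fixed columns then coverage/bases/qualities per cell) or from a pair of
tab-separated integer matrices with a loci table. Outputs are VCF v4.2 (via
pysam), a Newick tree and a JSON run report.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, NamedTuple, Sequence

import numpy as np
import pysam

__all__ = [
    "Locus",
    "CountMatrices",
    "parse_mpileup",
    "prefilter_candidates",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_vcf",
    "write_outputs",
]

_BASES = "ACGT"


class Locus(NamedTuple):
    chrom: str
    pos: int  # 1-based, as in mpileup/VCF
    ref: str
    alt: str


@dataclass
class CountMatrices:
    """Paired N x M reference/variant count matrices with a missing-data mask.

    An entry is missing when its total coverage r+v falls below the
    ``min_coverage`` threshold λ (default 1, i.e. only zero-coverage entries
    are missing).
    """

    R: np.ndarray
    V: np.ndarray
    loci: list[Locus]
    cell_names: list[str]
    min_coverage: int = 1

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.int64)
        self.V = np.asarray(self.V, dtype=np.int64)
        if self.R.shape != self.V.shape or self.R.ndim != 2:
            raise ValueError("R and V must be equal-shape 2-D matrices")
        if np.any(self.R < 0) or np.any(self.V < 0):
            raise ValueError("read counts must be non-negative")
        n, m = self.R.shape
        if len(self.loci) != m:
            raise ValueError(f"got {len(self.loci)} loci for {m} matrix columns")
        if len(self.cell_names) != n:
            raise ValueError(f"got {len(self.cell_names)} cell names for {n} rows")

    @property
    def n_cells(self) -> int:
        return self.R.shape[0]

    @property
    def n_sites(self) -> int:
        return self.R.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        return self.R + self.V

    @property
    def missing_mask(self) -> np.ndarray:
        return self.coverage < self.min_coverage

    def subset_loci(self, index) -> "CountMatrices":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrices(
            R=self.R[:, index],
            V=self.V[:, index],
            loci=[self.loci[int(j)] for j in index],
            cell_names=list(self.cell_names),
            min_coverage=self.min_coverage,
        )


class MpileupError(ValueError):
    """Malformed mpileup input."""


def _count_bases(bases: str, line_no: int) -> dict[str, int]:
    """Count read symbols in one per-cell mpileup base string.

    Strips read-start (^ plus mapping quality), read-end ($) and indel
    (+n.../-n...) annotations; '.'/',' are reference matches, ACGT (any case)
    mismatches; '*', '<'/'>' and N are placeholders counted toward coverage
    but toward neither allele.
    """
    counts: dict[str, int] = {}
    i, n = 0, len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise MpileupError(f"line {line_no}: malformed indel in {bases!r}")
            i = j + int(bases[i + 1 : j])
            continue
        counts[ch] = counts.get(ch, 0) + 1
        i += 1
    return counts


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_mpileup(
    source,
    cell_names: Sequence[str],
    min_coverage: int = 1,
) -> CountMatrices:
    """Parse mpileup text into per-cell reference/variant count matrices.

    The variant allele of a locus is the non-reference base with the highest
    pooled count across all cells (ties broken A<C<G<T); sites whose pooled
    non-reference count is zero carry no variant allele and are dropped with
    a warning. Base qualities are ignored: the model consumes counts only.

    Parameters
    ----------
    source : path or text stream
        mpileup text; ``.gz`` paths are decompressed transparently.
    cell_names : sequence of str
        One name per pileup sample column triple, in file order.
    min_coverage : int
        Missing-data threshold λ: entries with r+v < λ are flagged missing.
    """
    names = list(cell_names)
    n = len(names)
    r_rows: list[list[int]] = []
    v_rows: list[list[int]] = []
    loci: list[Locus] = []
    dropped = 0
    fh = _open_text(source)
    for line_no, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 3 + 3 * n:
            raise MpileupError(
                f"line {line_no}: expected {3 + 3 * n} columns for {n} cells, "
                f"got {len(fields)}"
            )
        chrom, pos, ref = fields[0], int(fields[1]), fields[2].upper()
        per_cell: list[dict[str, int]] = []
        for i in range(n):
            cov = int(fields[3 + 3 * i])
            bases = fields[4 + 3 * i]
            if cov == 0:
                per_cell.append({})
                continue
            counts = _count_bases(bases, line_no)
            if sum(counts.values()) != cov:
                raise MpileupError(
                    f"line {line_no}, cell {names[i]!r}: base string implies "
                    f"{sum(counts.values())} reads but coverage column says {cov}"
                )
            per_cell.append(counts)
        pooled = {b: 0 for b in _BASES if b != ref}
        for counts in per_cell:
            for b in pooled:
                pooled[b] += counts.get(b, 0) + counts.get(b.lower(), 0)
        if not pooled or max(pooled.values(), default=0) == 0:
            dropped += 1
            continue
        alt = max(sorted(pooled), key=lambda b: pooled[b])  # ties -> A<C<G<T
        r_rows.append([c.get(".", 0) + c.get(",", 0) for c in per_cell])
        v_rows.append([c.get(alt, 0) + c.get(alt.lower(), 0) for c in per_cell])
        loci.append(Locus(chrom, pos, ref, alt))
    if dropped:
        warnings.warn(
            f"dropped {dropped} site(s) with no variant-supporting reads",
            stacklevel=2,
        )
    m = len(loci)
    R = np.array(r_rows, dtype=np.int64).T.reshape(n, m)
    V = np.array(v_rows, dtype=np.int64).T.reshape(n, m)
    return CountMatrices(R=R, V=V, loci=loci, cell_names=names, min_coverage=min_coverage)


def prefilter_candidates(
    counts: CountMatrices,
    min_total_variant: int = 0,
    min_cells_with_variant: int = 0,
) -> CountMatrices:
    """Keep loci with enough pooled variant evidence.

    A simple plumbing pre-filter for candidate loci: a locus is retained when
    its pooled variant reads reach ``min_total_variant`` and at least
    ``min_cells_with_variant`` cells have any variant read. Column order is
    preserved; thresholds (0, 0) are the identity.
    """
    if min_total_variant < 0 or min_cells_with_variant < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (counts.V.sum(axis=0) >= min_total_variant) & (
        (counts.V > 0).sum(axis=0) >= min_cells_with_variant
    )
    return counts.subset_loci(keep)


# -------------------------------------------------------------------------- #
# tab-separated count-matrix dialect: one loci table (chrom, pos, ref, alt)
# and the two matrices with cells as rows, loci as columns.


def write_counts_tsv(counts: CountMatrices, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "loci.tsv", "w") as f:
        f.write("chrom\tpos\tref\talt\n")
        for loc in counts.loci:
            f.write(f"{loc.chrom}\t{loc.pos}\t{loc.ref}\t{loc.alt}\n")
    header = "\t".join(["cell"] + [f"{l.chrom}:{l.pos}" for l in counts.loci])
    for name, M in (("ref_counts.tsv", counts.R), ("var_counts.tsv", counts.V)):
        with open(outdir / name, "w") as f:
            f.write(header + "\n")
            for i, cell in enumerate(counts.cell_names):
                f.write(cell + "\t" + "\t".join(str(x) for x in M[i]) + "\n")


def read_counts_tsv(indir, min_coverage: int = 1) -> CountMatrices:
    indir = Path(indir)
    loci: list[Locus] = []
    with open(indir / "loci.tsv") as f:
        next(f)
        for line in f:
            chrom, pos, ref, alt = line.rstrip("\n").split("\t")
            loci.append(Locus(chrom, int(pos), ref, alt))

    def load(name):
        cells, rows = [], []
        with open(indir / name) as f:
            next(f)
            for line in f:
                parts = line.rstrip("\n").split("\t")
                cells.append(parts[0])
                rows.append([int(x) for x in parts[1:]])
        return cells, np.array(rows, dtype=np.int64)

    cells, R = load("ref_counts.tsv")
    cells_v, V = load("var_counts.tsv")
    if cells != cells_v:
        raise ValueError("ref/var matrices list different cells")
    return CountMatrices(R=R, V=V, loci=loci, cell_names=cells, min_coverage=min_coverage)


# -------------------------------------------------------------------------- #
# result serialization


def write_vcf(path, counts: CountMatrices, G: np.ndarray) -> int:
    """Write called genotypes as VCF v4.2; one record per locus with any call.

    Genotypes at missing entries are still imposed by the tree placement and
    are reported as calls; the per-sample MS flag marks entries whose
    observation was missing (coverage below λ).
    """
    G = np.asarray(G)
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(loc.chrom for loc in counts.loci):
        header.contigs.add(chrom)
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                         ("Description", "Genotype (0/1 mutation present)")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "MS"), ("Number", "1"), ("Type", "Integer"),
                         ("Description", "1 if the observation was missing (coverage below threshold)")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                         ("Description", "Reference and variant read depths")]
    )
    header.add_samples(counts.cell_names)
    missing = counts.missing_mask
    n_records = 0
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, loc in enumerate(counts.loci):
            if not np.any(G[:, j] == 1):
                continue
            rec = vcf.new_record(
                contig=loc.chrom, start=loc.pos - 1, stop=loc.pos,
                alleles=(loc.ref, loc.alt),
            )
            for i, cell in enumerate(counts.cell_names):
                rec.samples[cell]["GT"] = (0, 1) if G[i, j] == 1 else (0, 0)
                rec.samples[cell]["MS"] = int(missing[i, j])
                rec.samples[cell]["AD"] = (int(counts.R[i, j]), int(counts.V[i, j]))
            vcf.write(rec)
            n_records += 1
    return n_records


def write_outputs(results, counts: CountMatrices, outdir) -> dict[str, Path]:
    """Write VCF, Newick and JSON report for a finished fit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "calls.vcf",
        "newick": outdir / "tree.nwk",
        "report": outdir / "report.json",
    }
    n_records = write_vcf(paths["vcf"], counts, results.genotypes)
    paths["newick"].write_text(results.tree.to_newick() + "\n")
    report = {
        "log_likelihood": results.loglik,
        "alpha": results.alpha,
        "beta": results.beta,
        "iterations": results.n_iter,
        "seed": results.seed,
        "n_cells": counts.n_cells,
        "n_loci": counts.n_sites,
        "n_snv_sites": n_records,
    }
    paths["report"].write_text(json.dumps(report, indent=2) + "\n")
    return paths
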