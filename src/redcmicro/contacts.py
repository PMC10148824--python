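"""Gene assignment, per-RNA profiles, binned contact maps, replicate merging."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .core_genome import Gene, opposite_strand


def _strand_trees(genes, L: int):
    """One interval tree per gene strand; wrap-around genes split at the origin."""
    trees = {"+": IntervalTree(), "-": IntervalTree()}
    for g in genes:
        if g.wraps:
            trees[g.strand][g.start:L] = g
            if g.end > 0:
                trees[g.strand][0:g.end] = g
        else:
            trees[g.strand][g.start:g.end] = g
    return trees


def assign_rna_to_genes(contacts: pd.DataFrame, genes, L: int) -> pd.DataFrame:
    """Annotate contacts with their source gene.

    A contact is assigned to a gene when the RNA 3'-portion end overlaps the
    gene body and the RNA strand is the complement of the gene strand (the
    strand-specificity of the bridge-ligation chemistry). Contacts overlapping
    two qualifying genes are left unassigned (ambiguous), as are intergenic
    and wrong-strand contacts.
    """
    gene_ids = np.full(len(contacts), None, dtype=object)
    classes = np.full(len(contacts), None, dtype=object)
    ambiguous = np.zeros(len(contacts), dtype=bool)
    pos = contacts["rna3_pos"].to_numpy()
    strands = contacts["rna3_strand"].to_numpy() if "rna3_strand" in contacts else contacts["rna_strand"].to_numpy()

    by_strand = {"+": [g for g in genes if g.strand == "+"],
                 "-": [g for g in genes if g.strand == "-"]}
    if all(_non_overlapping(gs, L) for gs in by_strand.values()):
        # vectorized path: within each strand genes are disjoint, so no ambiguity
        for gstrand, gs in by_strand.items():
            if not gs:
                continue
            starts, ends, ids, cls = _sorted_arrays(gs, L)
            m = strands == opposite_strand(gstrand)
            idx = np.searchsorted(starts, pos[m], side="right") - 1
            idx = np.maximum(idx, 0)
            covered = (pos[m] >= starts[idx]) & (pos[m] < ends[idx])
            tgt = np.nonzero(m)[0][covered]
            gene_ids[tgt] = ids[idx[covered]]
            classes[tgt] = cls[idx[covered]]
    else:
        trees = _strand_trees(genes, L)
        for i in range(len(contacts)):
            hits = trees[opposite_strand(strands[i])][int(pos[i])]
            found = {iv.data.id: iv.data for iv in hits}
            if len(found) == 1:
                g = next(iter(found.values()))
                gene_ids[i] = g.id
                classes[i] = g.rna_class
            elif len(found) > 1:
                ambiguous[i] = True
    out = contacts.copy()
    out["gene_id"] = gene_ids
    out["rna_class"] = classes
    out["ambiguous"] = ambiguous
    return out


def _split_wrapped(genes, L: int):
    """(start, end, gene) triples with wrap-around genes split at the origin."""
    out = []
    for g in genes:
        if g.wraps:
            out.append((g.start, L, g))
            if g.end > 0:
                out.append((0, g.end, g))
        else:
            out.append((g.start, g.end, g))
    return sorted(out, key=lambda t: t[0])


def _non_overlapping(genes, L: int) -> bool:
    triples = _split_wrapped(genes, L)
    return all(a[1] <= b[0] for a, b in zip(triples, triples[1:]))


def _sorted_arrays(genes, L: int):
    triples = _split_wrapped(genes, L)
    starts = np.array([t[0] for t in triples], dtype=np.int64)
    ends = np.array([t[1] for t in triples], dtype=np.int64)
    ids = np.array([t[2].id for t in triples], dtype=object)
    cls = np.array([t[2].rna_class for t in triples], dtype=object)
    return starts, ends, ids, cls


@dataclass
class ContactMatrix:
    """Binned RNA-source x DNA-target count matrix (sparse CSR)."""

    bin_size: int
    L: int
    counts: sp.csr_matrix

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path) -> None:
        coo = self.counts.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w") as fh:
            fh.write(f"# L={self.L} bin_size={self.bin_size}\n")
            fh.write("row_bin\tcol_bin\tcount\n")
            for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                fh.write(f"{r}\t{c}\t{v}\n")

    @classmethod
    def from_tsv(cls, path) -> "ContactMatrix":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
        L, bin_size = int(meta["L"]), int(meta["bin_size"])
        df = pd.read_csv(path, sep="\t", skiprows=1)
        n = -(-L // bin_size)
        counts = sp.coo_matrix(
            (df["count"], (df["row_bin"], df["col_bin"])), shape=(n, n), dtype=np.int64
        ).tocsr()
        return cls(bin_size=bin_size, L=L, counts=counts)

    def pearson(self, other: "ContactMatrix") -> float:
        if self.counts.shape != other.counts.shape or self.bin_size != other.bin_size:
            raise ValueError("matrices differ in shape or bin size")
        x, y = self.counts.astype(float), other.counts.astype(float)
        n = x.shape[0] * x.shape[1]
        sx, sy = x.sum(), y.sum()
        sxx = x.multiply(x).sum()
        syy = y.multiply(y).sum()
        sxy = x.multiply(y).sum()
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        if den == 0:
            raise ValueError("undefined correlation: zero variance")
        return float(num / den)


def build_contact_map(contacts: pd.DataFrame, L: int, bin_size: int = 100) -> ContactMatrix:
    """Bin contacts into a ContactMatrix; row = RNA 3'-end bin, col = DNA-anchor bin."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n = -(-L // bin_size)
    rows = contacts["rna3_pos"].to_numpy() // bin_size
    cols = contacts["dna_pos"].to_numpy() // bin_size
    counts = sp.coo_matrix(
        (np.ones(len(contacts), dtype=np.int64), (rows, cols)), shape=(n, n)
    ).tocsr()
    return ContactMatrix(bin_size=bin_size, L=L, counts=counts)


def merge_replicates(map_a: ContactMatrix, map_b: ContactMatrix):
    """Element-wise sum of replicate maps plus their Pearson similarity."""
    if (map_a.bin_size, map_a.L) != (map_b.bin_size, map_b.L):
        raise ValueError("replicate maps differ in bin size or genome length")
    merged = ContactMatrix(
        bin_size=map_a.bin_size, L=map_a.L, counts=(map_a.counts + map_b.counts).tocsr()
    )
    try:
        r = map_a.pearson(map_b)
    except ValueError:  # one replicate constant (e.g. empty): similarity undefined
        r = float("nan")
    return merged, r


def build_rna_profile(
    contacts: pd.DataFrame, gene_id: str, L: int, bin_size: int = 100, genes=None
) -> np.ndarray:
    """Whole-genome DNA-anchor count vector for one RNA (all contacts of a gene)."""
    if genes is not None and gene_id not in {g.id for g in genes}:
        raise KeyError(f"unknown gene {gene_id!r}")
    if "gene_id" not in contacts:
        raise ValueError("contacts must be gene-assigned first")
    sub = contacts[contacts["gene_id"] == gene_id]
    if genes is None and len(sub) == 0 and gene_id not in set(contacts["gene_id"].dropna()):
        raise KeyError(f"unknown gene {gene_id!r}")
    n = -(-L // bin_size)
    profile = np.zeros(n, dtype=np.int64)
    if len(sub):
        np.add.at(profile, sub["dna_pos"].to_numpy() // bin_size, 1)
    return profile
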