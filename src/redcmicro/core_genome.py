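"""Genome and annotation data model for single circular replicons.

All internal coordinates are 0-based half-open; GFF3 input/output converts at
the boundary (GFF is 1-based closed). Every positional computation is modular
in the genome length ``L``: the replicon is circular and the distance between
two loci is the length of the shorter arc between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_CLASSES = ("mRNA", "rRNA16S", "rRNA23S", "rRNA5S", "tRNA", "6S", "other")
RRNA_CLASSES = frozenset({"rRNA16S", "rRNA23S", "rRNA5S"})


class GenomeFormatError(ValueError):
    """Malformed or unsupported genome input (zero/multiple records, empty sequence)."""


class AnnotationError(ValueError):
    """Annotation coordinates or attributes inconsistent with the genome."""


def opposite_strand(strand: str) -> str:
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    raise AnnotationError(f"unknown strand {strand!r}")


@dataclass(frozen=True)
class Genome:
    """A single circular replicon of length ``length`` (bp), optionally with sequence."""

    name: str
    length: int
    circular: bool = True
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.length <= 0:
            raise GenomeFormatError("genome length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise GenomeFormatError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end) with circular wrap-around; end may exceed L."""
        if self.sequence is None:
            raise GenomeFormatError("genome has no sequence")
        L = self.length
        start %= L
        if end - start > L:
            raise ValueError("requested slice longer than genome")
        end = start + (end - start)
        if end <= L:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - L]


@dataclass(frozen=True)
class Gene:
    id: str
    start: int
    end: int
    strand: str
    rna_class: str = "mRNA"
    wraps: bool = False  # start > end permitted only on circular replicons

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.rna_class not in RNA_CLASSES:
            raise AnnotationError(f"gene {self.id}: bad rna_class {self.rna_class!r}")
        if not self.wraps and not self.start < self.end:
            raise AnnotationError(f"gene {self.id}: start must be < end unless wrapping")

    def span(self, L: int) -> int:
        return (self.end - self.start) % L if self.wraps else self.end - self.start

    def middle(self, L: int) -> int:
        return gene_middle(self, L)

    def contains(self, pos: int | np.ndarray, L: int):
        """Membership in the gene body [start, end), circular-aware."""
        off = (np.asarray(pos) - self.start) % L
        return off < self.span(L)


@dataclass(frozen=True)
class Operon:
    """Ordered block of co-transcribed genes; gene_ids follow transcription order."""

    id: str
    gene_ids: tuple
    start: int
    end: int
    strand: str

    def span(self, L: int) -> int:
        return (self.end - self.start) % L


def gene_middle(gene: Gene, L: int) -> int:
    """Midpoint of the gene body, floor on ties; modular for wrap-around genes."""
    return (gene.start + gene.span(L) // 2) % L


def circular_distance(a, b, L: int):
    """Shortest-arc distance between coordinates on a circle of length L.

    Computes d1 = |a - b| and d2 = |d1 - L| and returns the lesser; the result
    lies in [0, L/2]. Accepts scalars or arrays.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if np.any(a < 0) or np.any(a >= L) or np.any(b < 0) or np.any(b >= L):
        raise ValueError(f"coordinates outside [0, {L})")
    d1 = np.abs(a - b)
    d2 = np.abs(d1 - L)
    out = np.minimum(d1, d2)
    return out if out.ndim else int(out)


# ---------------------------------------------------------------------------
# FASTA


def load_genome(path) -> Genome:
    """Read a genome FASTA holding exactly one circular replicon."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenomeFormatError(
            f"{path}: expected exactly one replicon, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise GenomeFormatError(f"{path}: empty sequence")
    return Genome(name=rec.id, length=len(seq), circular=True, sequence=seq)


def write_genome(genome: Genome, path) -> None:
    if genome.sequence is None:
        raise GenomeFormatError("cannot write a genome without sequence")
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="circular")
    SeqIO.write([rec], str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / BED annotation

# Feature-type -> rna_class mapping used when no explicit rna_class attribute is
# present. rRNA subunits are resolved from the product/Name attribute; ncRNAs
# whose name mentions 6S or ssrS are taken as 6S RNA.
_MRNA_TYPES = {"gene", "CDS", "mRNA", "protein_coding_gene"}


def _classify_feature(ftype: str, attrs: dict) -> str:
    def attr(*keys):
        for k in keys:
            v = attrs.get(k)
            if v:
                return v[0] if isinstance(v, (list, tuple)) else v
        return ""

    explicit = attr("rna_class")
    if explicit:
        if explicit not in RNA_CLASSES:
            raise AnnotationError(f"unknown rna_class attribute {explicit!r}")
        return explicit
    label = " ".join([attr("product", "Name", "gene"), ftype])
    if ftype == "tRNA":
        return "tRNA"
    if ftype == "rRNA":
        for sub in ("16S", "23S", "5S"):
            if sub in label:
                return f"rRNA{sub}"
        return "other"
    if ftype == "ncRNA":
        if "6S" in label or "ssrS" in label or "ssra" in label.lower():
            return "6S"
        return "other"
    if ftype in _MRNA_TYPES:
        return "mRNA"
    return "other"


def _parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def load_annotation(path, genome: Genome, operon_tsv=None):
    """Read genes (GFF3 or BED6) and operons (GFF3 ``operon`` features or sidecar TSV).

    Returns ``(genes, operons)`` with all coordinates normalized to 0-based
    half-open. GFF coordinates are validated against [1, L]; BED against [0, L).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        genes, operons = _load_bed(path, genome), []
    else:
        genes, operons = _load_gff(path, genome)
    if operon_tsv is not None:
        operons = load_operons_tsv(operon_tsv)
    _check_operons(genes, operons)
    return genes, operons


def _load_gff(path, genome: Genome):
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=False,
    )
    genes, operon_feats = [], []
    for f in db.all_features():
        if f.featuretype == "region":
            continue
        if not (1 <= f.start <= genome.length and 1 <= f.end <= genome.length):
            raise AnnotationError(
                f"{f.id}: coordinates {f.start}-{f.end} outside [1, {genome.length}]"
            )
        if f.start > f.end:
            raise AnnotationError(f"{f.id}: wrap-around features unsupported in GFF input")
        if f.featuretype == "operon":
            operon_feats.append(f)
            continue
        attrs = {k: v for k, v in f.attributes.items()}
        gid = f.id or (attrs.get("ID") or [None])[0]
        if gid is None:
            raise AnnotationError(f"feature at {f.start} lacks an ID")
        genes.append(
            Gene(
                id=gid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                rna_class=_classify_feature(f.featuretype, attrs),
            )
        )
    operons = []
    for f in operon_feats:
        # gffutils splits multi-valued attributes on commas already
        vals = list(f.attributes.get("genes", []))
        gene_ids = tuple(vals[0].split(",")) if len(vals) == 1 else tuple(vals)
        operons.append(
            Operon(
                id=f.id, gene_ids=gene_ids, start=f.start - 1, end=f.end, strand=f.strand
            )
        )
    return genes, operons


def _load_bed(path, genome: Genome):
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    genes = []
    for row in df.itertuples(index=False):
        if not (0 <= row.start < row.end <= genome.length):
            raise AnnotationError(
                f"{row.name}: BED coordinates {row.start}-{row.end} outside [0, {genome.length})"
            )
        genes.append(
            Gene(id=str(row.name), start=int(row.start), end=int(row.end),
                 strand=str(getattr(row, "strand", "+")))
        )
    return genes


def write_annotation_gff(genes, operons, genome: Genome, path) -> None:
    """Write genes/operons as GFF3 with explicit rna_class attributes (round-trips)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
        for g in genes:
            if g.wraps:
                raise AnnotationError("wrap-around genes cannot be written to GFF3")
            ftype = {"tRNA": "tRNA", "6S": "ncRNA"}.get(g.rna_class, None)
            if ftype is None:
                ftype = "rRNA" if g.rna_class in RRNA_CLASSES else "gene"
            fh.write(
                f"{genome.name}\tredcmicro\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id};rna_class={g.rna_class}\n"
            )
        for op in operons:
            fh.write(
                f"{genome.name}\tredcmicro\toperon\t{op.start + 1}\t{op.end}\t.\t"
                f"{op.strand}\t.\tID={op.id};genes={','.join(op.gene_ids)}\n"
            )


def load_operons_tsv(path):
    df = pd.read_csv(path, sep="\t")
    operons = []
    for oid, grp in df.groupby("operon_id", sort=False):
        grp = grp.sort_values("rank")
        strands = set(grp["strand"])
        if len(strands) != 1:
            raise AnnotationError(f"operon {oid}: member genes on mixed strands")
        operons.append(
            Operon(
                id=str(oid),
                gene_ids=tuple(grp["gene_id"].astype(str)),
                start=int(grp["start"].iloc[0]),
                end=int(grp["end"].iloc[0]),
                strand=strands.pop(),
            )
        )
    return operons


def write_operons_tsv(operons, path) -> None:
    rows = []
    for op in operons:
        for rank, gid in enumerate(op.gene_ids):
            rows.append((op.id, gid, rank, op.start, op.end, op.strand))
    pd.DataFrame(
        rows, columns=["operon_id", "gene_id", "rank", "start", "end", "strand"]
    ).to_csv(path, sep="\t", index=False)


def _check_operons(genes, operons):
    by_id = {g.id: g for g in genes}
    for op in operons:
        for gid in op.gene_ids:
            g = by_id.get(gid)
            if g is None:
                raise AnnotationError(f"operon {op.id}: unknown gene {gid}")
            if g.strand != op.strand:
                raise AnnotationError(f"operon {op.id}: gene {gid} on opposite strand")


def genes_to_frame(genes, L: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.id for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "rna_class": [g.rna_class for g in genes],
            "length": [g.span(L) for g in genes],
            "middle": [g.middle(L) for g in genes],
        }
    )
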