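"""From raw bridge-containing read pairs to unique RNA-DNA contacts.

The filtering cascade:

1. scan each pair for the bridge (forward read) and the GGG tag (reverse
   read); split the forward read into DNA portion (upstream of the bridge)
   and RNA 3' portion (downstream, trimmed at the template-switch trace), and
   take the RNA 5' portion downstream of the first GGG;
2. keep DNA portions of 18-20 nt and RNA portions of >=10 nt; reattach the
   CATG lost at the NlaIII junction to the DNA portion (18-20 -> 22-24 nt);
3. map the three portions independently and exactly, counting occurrences on
   both strands; keep triples where all three map uniquely;
4. discard template-switch artifacts: RNA 3'/5' portions more than 10 kb
   apart (circular distance) or on the same strand.

The exact-match unique mapper is adequate for synthetic genomes; externally
produced alignments (SAM) can be ingested instead for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .core_genome import Genome, circular_distance
from .synthetic_data import revcomp

MIN_DNA, MAX_DNA = 18, 20
MIN_RNA = 10
MAX_RNA_SEPARATION = 10_000


@dataclass
class PortionTriple:
    read_id: str
    dna_seq: str
    rna3_seq: str
    rna5_seq: str
    dna_offset: int = 0
    rna3_offset: int = 0
    rna5_offset: int = 0


@dataclass(frozen=True)
class MapResult:
    status: str  # unique | multi | unmapped
    pos: int = -1  # leftmost matched base on the forward strand
    strand: str = "."
    length: int = 0


@dataclass
class MappedTriple:
    dna: MapResult
    rna3: MapResult
    rna5: MapResult


@dataclass
class ProcessingStats:
    """Read-pair survival after each consecutive pipeline step (monotone)."""

    total: int = 0
    bridge_ggg_found: int = 0
    length_pass: int = 0
    triple_unique: int = 0
    accepted: int = 0
    rejections: dict = field(default_factory=dict)

    def count_rejection(self, reason: str):
        self.rejections[reason] = self.rejections.get(reason, 0) + 1

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "total": self.total,
                "bridge_ggg_found": self.bridge_ggg_found,
                "length_pass": self.length_pass,
                "triple_unique": self.triple_unique,
                "accepted": self.accepted,
            }
        )


def _find_with_mismatch(seq: str, pattern: str, max_mismatch: int) -> int:
    """Leftmost occurrence of pattern allowing up to max_mismatch substitutions."""
    if max_mismatch <= 0:
        return seq.find(pattern)
    n, m = len(seq), len(pattern)
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(seq[i : i + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return i
    return -1


def scan_read_pair(
    fwd: str,
    rev: str,
    bridge: str,
    max_mismatch: int = 0,
    ggg: str = "GGG",
    trim_tag: str = "CCC",
    read_id: str = "",
):
    """Split a read pair into its three portions, or return a rejection reason.

    The DNA portion is the forward read upstream of the first bridge
    occurrence; the RNA 3' portion is everything downstream of the bridge,
    truncated at the first ``trim_tag`` occurrence if present; the RNA 5'
    portion is the reverse read downstream of the first GGG. Returns a
    :class:`PortionTriple` or a string reason (``no_bridge`` / ``no_ggg``) —
    rejections are data, not errors.
    """
    i = _find_with_mismatch(fwd, bridge, max_mismatch)
    if i == -1:
        return "no_bridge"
    g = rev.find(ggg)
    if g == -1:
        return "no_ggg"
    rna3 = fwd[i + len(bridge) :]
    t = rna3.find(trim_tag)
    if t != -1:
        rna3 = rna3[:t]
    return PortionTriple(
        read_id=read_id,
        dna_seq=fwd[:i],
        rna3_seq=rna3,
        rna5_seq=rev[g + len(ggg) :],
        dna_offset=0,
        rna3_offset=i + len(bridge),
        rna5_offset=g + len(ggg),
    )


def reattach_catg(dna_seq: str) -> str:
    """Reappend the blunted NlaIII overhang: an 18-20 nt portion becomes 22-24 nt."""
    if not MIN_DNA <= len(dna_seq) <= MAX_DNA:
        raise ValueError(
            f"DNA portion length {len(dna_seq)} outside [{MIN_DNA}, {MAX_DNA}]"
        )
    return dna_seq + "CATG"


class GenomeIndex:
    """Exact-match occurrence counter over both strands of a circular genome.

    Seeds queries with their leading k-mer against a sorted k-mer table of all
    L start positions (built over the wrap-extended sequence), then verifies
    candidates by direct string comparison. ``unique`` means exactly one exact
    occurrence counting both strands; reverse-strand hits are reported at the
    forward-strand coordinate of the match's leftmost base.
    """

    _CODE = np.full(256, -1, dtype=np.int64)
    for _i, _c in enumerate(b"ACGT"):
        _CODE[_c] = _i

    def __init__(self, genome: Genome, k: int = 10, max_query: int = 300):
        if genome.sequence is None:
            raise ValueError("genome index requires a sequence")
        self.L = genome.length
        self.k = k
        self._seq = genome.sequence + genome.sequence[: max_query + k]
        codes = self._CODE[np.frombuffer(self._seq.encode(), dtype=np.uint8)]
        if np.any(codes[: self.L] < 0):
            codes = np.where(codes < 0, 0, codes)  # Ns never verify anyway
        kmers = np.zeros(self.L, dtype=np.int64)
        for j in range(k):
            kmers = kmers * 4 + codes[j : j + self.L]
        order = np.argsort(kmers, kind="stable")
        self._sorted = kmers[order]
        self._positions = order.astype(np.int64)

    def _encode(self, seq: str) -> int:
        code = 0
        for ch in seq:
            v = self._CODE[ord(ch)]
            if v < 0:
                return -1
            code = code * 4 + int(v)
        return code

    def _occurrences_one_strand(self, seq: str) -> list[int]:
        code = self._encode(seq[: self.k])
        if code < 0:
            return []
        lo = np.searchsorted(self._sorted, code, side="left")
        hi = np.searchsorted(self._sorted, code, side="right")
        hits = []
        for p in self._positions[lo:hi]:
            p = int(p)
            if self._seq[p : p + len(seq)] == seq:
                hits.append(p % self.L)
        return hits

    def occurrences(self, seq: str) -> list[tuple[int, str]]:
        if len(seq) < self.k:
            raise ValueError(f"query shorter than index k-mer ({self.k})")
        out = [(p, "+") for p in sorted(set(self._occurrences_one_strand(seq)))]
        out += [(p, "-") for p in sorted(set(self._occurrences_one_strand(revcomp(seq))))]
        return out

    def map_portion(self, seq: str) -> MapResult:
        occ = self.occurrences(seq)
        if not occ:
            return MapResult("unmapped", length=len(seq))
        if len(occ) > 1:
            return MapResult("multi", length=len(seq))
        pos, strand = occ[0]
        return MapResult("unique", pos=pos, strand=strand, length=len(seq))


def map_portion(seq: str, genome_index: GenomeIndex, strategy: str = "exact") -> MapResult:
    if strategy != "exact":
        raise ValueError(f"unknown mapping strategy {strategy!r}")
    return genome_index.map_portion(seq)


def filter_triple(mapped: MappedTriple, L: int, max_separation: int = MAX_RNA_SEPARATION):
    """Accept a mapped triple or reject it with a reason code.

    Accept iff all three portions are unique, the RNA 3'/5' portions lie
    within ``max_separation`` (circular distance) and map to opposite strands.
    """
    for res in (mapped.dna, mapped.rna3, mapped.rna5):
        if res.status != "unique":
            return False, "not_unique"
    r3 = _portion_anchor(mapped.rna3, L, three_prime=True)
    r5 = _portion_anchor(mapped.rna5, L, three_prime=False)
    if circular_distance(r3, r5, L) > max_separation:
        return False, "far_apart"
    if mapped.rna3.strand == mapped.rna5.strand:
        return False, "same_strand"
    return True, "ok"


def _portion_anchor(res: MapResult, L: int, three_prime: bool) -> int:
    """Genomic coordinate of the biologically meaningful end of a portion.

    The first base of the RNA 3' portion in the read is the RNA fragment's 3'
    end; the first base after GGG in the reverse read is the segment's 5'-most
    base. For a forward-strand match the read's first base sits at the
    leftmost coordinate; for a reverse-strand match at the rightmost.
    """
    del three_prime  # both portions anchor on the read's first base
    if res.strand == "+":
        return res.pos
    return (res.pos + res.length - 1) % L


def _dna_anchor(res: MapResult, L: int) -> int:
    """Coordinate of the DNA-portion end adjoining the NlaIII site (the read's
    last base: the reattached CATG abuts the bridge)."""
    if res.strand == "+":
        return (res.pos + res.length - 1) % L
    return res.pos


CONTACT_COLUMNS = [
    "read_id", "rna3_pos", "rna3_strand", "rna5_pos", "rna5_strand",
    "dna_pos", "dna_strand",
]


def process_run(
    fastq_fwd,
    fastq_rev,
    genome: Genome,
    bridge: str,
    *,
    switch_oligo: str | None = None,
    ggg: str = "GGG",
    max_mismatch: int = 0,
    max_separation: int = MAX_RNA_SEPARATION,
    index: GenomeIndex | None = None,
):
    """Run the full cascade on a FASTQ pair; returns (contacts, ProcessingStats).

    When the switch oligo is known, RNA 3' trimming anchors on the full
    template-switch trace (``CCC`` + switch-oligo prefix) rather than any bare
    G-triplet, so genomic C/G runs inside the transcript are not mistaken for
    the read-through boundary.
    """
    trim_tag = "CCC" + switch_oligo[:6] if switch_oligo else "CCC"
    if index is None:
        index = GenomeIndex(genome)
    L = genome.length
    stats = ProcessingStats()
    rows = []

    with pysam.FastxFile(str(fastq_fwd)) as f1, pysam.FastxFile(str(fastq_rev)) as f2:
        for e1, e2 in zip(f1, f2):
            stats.total += 1
            res = scan_read_pair(
                e1.sequence, e2.sequence, bridge,
                max_mismatch=max_mismatch, ggg=ggg, trim_tag=trim_tag,
                read_id=e1.name,
            )
            if isinstance(res, str):
                stats.count_rejection(res)
                continue
            stats.bridge_ggg_found += 1
            if not MIN_DNA <= len(res.dna_seq) <= MAX_DNA:
                stats.count_rejection("dna_length")
                continue
            if len(res.rna3_seq) < MIN_RNA or len(res.rna5_seq) < MIN_RNA:
                stats.count_rejection("rna_short")
                continue
            stats.length_pass += 1
            mapped = MappedTriple(
                dna=index.map_portion(reattach_catg(res.dna_seq)),
                rna3=index.map_portion(res.rna3_seq),
                rna5=index.map_portion(res.rna5_seq),
            )
            if any(m.status != "unique" for m in (mapped.dna, mapped.rna3, mapped.rna5)):
                stats.count_rejection("not_unique")
                continue
            stats.triple_unique += 1
            ok, reason = filter_triple(mapped, L, max_separation)
            if not ok:
                stats.count_rejection(reason)
                continue
            stats.accepted += 1
            rows.append(
                (
                    res.read_id,
                    _portion_anchor(mapped.rna3, L, True), mapped.rna3.strand,
                    _portion_anchor(mapped.rna5, L, False), mapped.rna5.strand,
                    _dna_anchor(mapped.dna, L), mapped.dna.strand,
                )
            )

    contacts = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    return contacts, stats


def write_contacts_tsv(contacts: pd.DataFrame, path) -> None:
    contacts.to_csv(path, sep="\t", index=False)


def read_contacts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def contacts_from_sam(sam_dna, sam_rna3, sam_rna5, L: int, max_separation: int = MAX_RNA_SEPARATION):
    """Escape hatch: assemble contacts from externally aligned portions (SAM).

    Each SAM must contain primary alignments of the respective portions keyed
    by read name; reads absent from any file or marked unmapped/secondary are
    dropped, then the standard proximity/strand filter applies.
    """
    def load(path):
        out = {}
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.query_name in out:
                    out[aln.query_name] = None  # multi-mapped
                    continue
                out[aln.query_name] = MapResult(
                    "unique",
                    pos=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    length=aln.query_length,
                )
        return {k: v for k, v in out.items() if v is not None}

    dna, r3, r5 = load(sam_dna), load(sam_rna3), load(sam_rna5)
    rows = []
    for name in sorted(set(dna) & set(r3) & set(r5)):
        mapped = MappedTriple(dna[name], r3[name], r5[name])
        ok, _ = filter_triple(mapped, L, max_separation)
        if ok:
            rows.append(
                (name,
                 _portion_anchor(mapped.rna3, L, True), mapped.rna3.strand,
                 _portion_anchor(mapped.rna5, L, False), mapped.rna5.strand,
                 _dna_anchor(mapped.dna, L), mapped.dna.strand)
            )
    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)
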