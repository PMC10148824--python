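"""Positional contact analyses on the circular genome.

Three views of where an RNA touches the chromosome relative to its gene:

* four concentric distance intervals around the encoding gene's middle
  (+/-5 kb; 5-50 kb; 50-500 kb; >500 kb), contact frequency per interval
  expressed relative to the RNA's genome-wide average frequency;
* upstream/downstream contact frequencies of mRNA fragments in exponentially
  growing distance bins ([0,64), [64,128), ...), resolved with respect to the
  transcription direction — the signature of nascent-transcript drag is a
  downstream/upstream ratio above 1 at short range;
* cumulative 24x24 operon contact maps (12 bins on the operon, 6 on each
  half-operon-length flank), summed separately for sense- and
  antisense-transcribed operons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_genome import Gene, circular_distance, gene_middle

CANONICAL_EDGES = (5_000, 50_000, 500_000)
MIN_CONTACTS = 500


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Four-interval cis/trans preference


@dataclass
class IntervalPreference:
    gene_id: str
    total: int
    counts: np.ndarray  # contacts per interval (4,)
    lengths: np.ndarray  # interval lengths after masking (4,)
    rel_freq: np.ndarray  # per-interval frequency / genome-average frequency
    masked_count: int = 0
    passed_filter: bool = True


def _ring_arcs(mid: int, lo: int, hi: int, L: int):
    """Genomic arcs (start, end) covering circular distances [lo, hi) from mid.

    ``hi`` may be L//2 + 1 to close the far ring. Arcs are returned unwrapped
    (coordinates may fall outside [0, L)); callers re-wrap as needed.
    """
    hi = min(hi, L // 2 + 1)
    if lo == 0:
        return [(mid - (hi - 1), mid + hi)]
    return [(mid + lo, mid + hi), (mid - (hi - 1), mid - lo + 1)]


def _arc_mask_overlap(arcs, mask, L: int) -> int:
    """Total bp of mask intervals falling inside the arcs (circular)."""
    total = 0
    for a0, a1 in arcs:
        b0 = a0 % L
        b1 = b0 + (a1 - a0)  # arc shifted into [0, 2L)
        for m0, m1 in mask:
            for shift in (0, L):
                total += max(0, min(b1, m1 + shift) - max(b0, m0 + shift))
    return total


def interval_preference(
    contacts: pd.DataFrame,
    gene: Gene,
    L: int,
    mask=None,
    edges=CANONICAL_EDGES,
    min_contacts: int = MIN_CONTACTS,
) -> IntervalPreference:
    """Relative contact frequency of one RNA in concentric distance intervals.

    Frequencies are counts divided by interval length (both sides pooled for
    the middle rings); the reference is the RNA's average frequency over the
    (unmasked) genome. ``mask`` is a list of genomic [start, end) intervals —
    e.g. multi-copy rRNA operons — removed from both counts and lengths, the
    flank-only variant used when parental-locus mappability is poor.
    """
    e1, e2, e3 = edges
    if L <= 2 * e3:
        raise ConfigurationError(
            f"genome length {L} too short for interval edges {edges}; supply custom edges"
        )
    sub = contacts[contacts["gene_id"] == gene.id] if "gene_id" in contacts else contacts
    mid = gene_middle(gene, L)
    d = np.asarray(circular_distance(sub["dna_pos"].to_numpy(), mid, L))

    lengths = np.array([2 * e1, 2 * (e2 - e1), 2 * (e3 - e2), L - 2 * e3], dtype=float)
    masked_count = 0
    dna = sub["dna_pos"].to_numpy()
    keep = np.ones(len(sub), dtype=bool)
    if mask:
        for m0, m1 in mask:
            span = (m1 - m0) % L or (m1 - m0)
            keep &= (dna - m0) % L >= span
        masked_count = int((~keep).sum())
        ring_bounds = [(0, e1), (e1, e2), (e2, e3), (e3, L // 2 + 1)]
        for i, (lo, hi) in enumerate(ring_bounds):
            arcs = _ring_arcs(mid, lo, hi, L)
            lengths[i] -= _arc_mask_overlap(arcs, mask, L)
    d = d[keep]

    idx = np.searchsorted(np.array(edges), d, side="right")
    counts = np.bincount(idx, minlength=4).astype(float)
    total = int(counts.sum())
    baseline = total / lengths.sum() if total else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (counts / lengths) / baseline
    return IntervalPreference(
        gene_id=gene.id,
        total=total,
        counts=counts.astype(int),
        lengths=lengths,
        rel_freq=rel,
        masked_count=masked_count,
        passed_filter=total + masked_count >= min_contacts,
    )


def interval_preference_table(
    contacts: pd.DataFrame, genes, L: int, mask=None, edges=CANONICAL_EDGES,
    min_contacts: int = MIN_CONTACTS,
) -> pd.DataFrame:
    """Per-RNA interval table for every RNA meeting the contact-count filter."""
    rows = []
    counts_by_gene = contacts["gene_id"].value_counts()
    for g in genes:
        if counts_by_gene.get(g.id, 0) < min_contacts:
            continue
        p = interval_preference(contacts, g, L, mask=mask, edges=edges,
                                min_contacts=min_contacts)
        rows.append(
            {
                "rna_id": g.id, "rna_class": g.rna_class, "total": p.total,
                **{f"count_I{i + 1}": p.counts[i] for i in range(4)},
                **{f"relfreq_I{i + 1}": p.rel_freq[i] for i in range(4)},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Upstream/downstream assignment (nascent-transcript drag)


def updown_assign(rna3_pos, dna_pos, gene_strand, L: int):
    """Side (upstream/downstream of the RNA 3' end, in transcription direction)
    and circular distance for each contact.

    Implements the full case table over the sign of rna - dna and the
    comparison of the direct (d1) and around-the-origin (d2) distances; the
    rna == dna tie has distance 0, is assigned via the d1 >= d2 branch
    convention (downstream for either strand) and flagged. Vectorized.

    Returns (side, distance, tie) arrays; side entries are "upstream" /
    "downstream".
    """
    rna = np.atleast_1d(np.asarray(rna3_pos, dtype=np.int64))
    dna = np.atleast_1d(np.asarray(dna_pos, dtype=np.int64))
    strand = np.atleast_1d(np.asarray(gene_strand))
    if not np.all((strand == "+") | (strand == "-")):
        raise ValueError("gene strand must be '+' or '-'")
    diff = rna - dna
    d1 = np.abs(diff)
    d2 = np.abs(d1 - L)
    dist = np.minimum(d1, d2)
    sense = strand == "+"
    near = d1 < d2
    up = (
        (sense & (diff > 0) & near)
        | (~sense & (diff < 0) & near)
        | (sense & (diff < 0) & ~near)
        | (~sense & (diff > 0) & ~near)
    )
    tie = diff == 0
    side = np.where(up & ~tie, "upstream", "downstream")
    if np.isscalar(rna3_pos) or np.ndim(rna3_pos) == 0:
        return str(side[0]), int(dist[0]), bool(tie[0])
    return side, dist, tie


def distance_bin_edges(L: int, base: int = 64) -> np.ndarray:
    """Exponential bin edges 0, base, 2*base, ... clipped to cover [0, L//2]."""
    edges = [0]
    e = base
    while e <= L // 2:
        edges.append(e)
        e *= 2
    edges.append(L // 2 + 1)
    return np.array(edges, dtype=np.int64)


def updown_frequency_profile(
    contacts: pd.DataFrame, genes, L: int, base: int = 64, include_ties: bool = True
) -> pd.DataFrame:
    """Upstream/downstream contact frequencies per exponential distance bin.

    Input contacts must be gene-assigned; only mRNA-class (proper-strand)
    contacts are used. Frequency is count per bp of bin width; the ratio
    column is downstream frequency / upstream frequency.
    """
    strand_of = {g.id: g.strand for g in genes}
    sub = contacts[(contacts["rna_class"] == "mRNA") & contacts["gene_id"].notna()]
    edges = distance_bin_edges(L, base)
    if len(sub) == 0:
        return pd.DataFrame(
            columns=["bin_lo", "bin_hi", "width", "up_count", "down_count",
                     "up_freq", "down_freq", "ratio", "tie_count"]
        )
    strands = sub["gene_id"].map(strand_of).to_numpy()
    side, dist, tie = updown_assign(
        sub["rna3_pos"].to_numpy(), sub["dna_pos"].to_numpy(), strands, L
    )
    if not include_ties:
        side, dist, tie = side[~tie], dist[~tie], tie[~tie]
    idx = np.searchsorted(edges, dist, side="right") - 1
    nb = len(edges) - 1
    up_counts = np.bincount(idx[side == "upstream"], minlength=nb)
    down_counts = np.bincount(idx[side == "downstream"], minlength=nb)
    tie_counts = np.bincount(idx[tie], minlength=nb) if include_ties else np.zeros(nb, int)
    widths = np.diff(edges).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        up_f = up_counts / widths
        down_f = down_counts / widths
        ratio = np.where(up_counts > 0, down_f / up_f, np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1], "bin_hi": edges[1:], "width": widths.astype(int),
            "up_count": up_counts, "down_count": down_counts,
            "up_freq": up_f, "down_freq": down_f, "ratio": ratio,
            "tie_count": tie_counts,
        }
    )


# ---------------------------------------------------------------------------
# Cumulative operon maps

OPERON_BINS = 24  # 12 on the operon + 6 per half-operon-length flank


@dataclass
class OperonMap:
    orientation: str  # sense | antisense
    counts: np.ndarray = field(default_factory=lambda: np.zeros((OPERON_BINS, OPERON_BINS), dtype=np.int64))
    n_operons: int = 0

    def mass_above_diagonal(self) -> int:
        return int(np.triu(self.counts, k=1).sum())

    def mass_below_diagonal(self) -> int:
        return int(np.tril(self.counts, k=-1).sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# orientation={self.orientation} n_operons={self.n_operons}\n")
            np.savetxt(fh, self.counts, fmt="%d", delimiter="\t")


def operon_cumulative_map(contacts: pd.DataFrame, operons, L: int) -> dict:
    """Sum per-operon 24x24 contact matrices by transcription orientation.

    Each operon window spans the operon plus half-operon-length flanks, split
    into 24 equal bins in genomic (unflipped) orientation; a contact whose RNA
    3' end and DNA anchor both fall in the window increments one cell.
    Contacts must be gene-assigned; only mRNA-class contacts contribute.
    """
    sub = contacts[(contacts["rna_class"] == "mRNA") & contacts["gene_id"].notna()]
    rna = sub["rna3_pos"].to_numpy()
    dna = sub["dna_pos"].to_numpy()
    maps = {"sense": OperonMap("sense"), "antisense": OperonMap("antisense")}
    for op in operons:
        olen = op.span(L)
        if olen == 0:
            warnings.warn(f"operon {op.id} has zero length; skipped")
            continue
        wstart = op.start - olen / 2.0
        wlen = 2.0 * olen
        width = wlen / OPERON_BINS
        roff = (rna - wstart) % L
        doff = (dna - wstart) % L
        inside = (roff < wlen) & (doff < wlen)
        if not inside.any():
            key = "sense" if op.strand == "+" else "antisense"
            maps[key].n_operons += 1
            continue
        rb = np.minimum((roff[inside] / width).astype(int), OPERON_BINS - 1)
        db = np.minimum((doff[inside] / width).astype(int), OPERON_BINS - 1)
        key = "sense" if op.strand == "+" else "antisense"
        np.add.at(maps[key].counts, (rb, db), 1)
        maps[key].n_operons += 1
    return maps
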