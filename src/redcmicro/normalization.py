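"""Background-normalized noncoding-RNA contacts with protein-coding genes.

The number of contacts a target RNA (pooled 16S/23S/5S rRNA, or 6S RNA)
establishes with a gene body confounds biology with gene length, local
cross-linking/digestion efficiency and mappability. Those technical factors
cancel when the count is divided by the gene's *nonspecific* contacts: mRNA
fragments transcribed more than 250 kb away that nevertheless ligated to this
gene. Genes with fewer than 10 background contacts are excluded as
unquantifiable. Transcriptional activity of a gene is estimated from its own
mRNA's contacts within +/-5 kb of the gene middle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core_genome import Gene, RRNA_CLASSES, circular_distance, gene_middle

ACTIVITY_RADIUS = 5_000  # closed edge: a contact at exactly 5,000 bp counts
BACKGROUND_MIN_DISTANCE = 250_000
MIN_BACKGROUND = 10


class ConfigurationError(ValueError):
    pass


def gene_activity(contacts: pd.DataFrame, gene: Gene, L: int,
                  radius: int = ACTIVITY_RADIUS) -> int:
    """Contacts of the gene's own mRNA anchored within ``radius`` of its middle."""
    if "gene_id" not in contacts:
        raise ValueError("contacts must be gene-assigned first")
    sub = contacts[contacts["gene_id"] == gene.id]
    if len(sub) == 0 and gene.id not in set(contacts["gene_id"].dropna()):
        # still a valid query; zero contacts is an answer, unknown gene is not
        pass
    mid = gene_middle(gene, L)
    d = np.asarray(circular_distance(sub["dna_pos"].to_numpy(), mid, L))
    return int((d <= radius).sum())


def background_count(contacts: pd.DataFrame, gene: Gene, L: int,
                     min_distance: int = BACKGROUND_MIN_DISTANCE) -> int:
    """mRNA contacts landing in the gene body whose source lies > min_distance away.

    The source position is the mapped RNA 3' end; distance is circular to the
    gene middle. Raises when the genome is too short to contain a distal
    region at all.
    """
    if L <= 2 * min_distance:
        raise ConfigurationError(
            f"genome length {L} leaves no region beyond {min_distance} bp"
        )
    sub = contacts[(contacts["rna_class"] == "mRNA") & contacts["gene_id"].notna()]
    mid = gene_middle(gene, L)
    in_body = gene.contains(sub["dna_pos"].to_numpy(), L)
    far = np.asarray(circular_distance(sub["rna3_pos"].to_numpy(), mid, L)) > min_distance
    return int((in_body & far).sum())


def _pc_gene_of_anchor(contacts_pos: np.ndarray, pc_genes, L: int):
    """Map each DNA anchor to the protein-coding gene(s) covering it.

    Returns (contact_index, gene_index) arrays; anchors inside two overlapping
    genes contribute one pair per gene.
    """
    from .contacts import _non_overlapping, _split_wrapped

    if _non_overlapping(pc_genes, L):
        triples = _split_wrapped(pc_genes, L)
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        idx_of = {g.id: i for i, g in enumerate(pc_genes)}
        owner = np.array([idx_of[t[2].id] for t in triples], dtype=np.int64)
        j = np.maximum(np.searchsorted(starts, contacts_pos, side="right") - 1, 0)
        covered = (contacts_pos >= starts[j]) & (contacts_pos < ends[j])
        return np.nonzero(covered)[0], owner[j[covered]]

    tree = IntervalTree()
    for gi, g in enumerate(pc_genes):
        if g.wraps:
            tree[g.start:L] = gi
            if g.end > 0:
                tree[0:g.end] = gi
        else:
            tree[g.start:g.end] = gi
    ci, gi = [], []
    for i, p in enumerate(contacts_pos):
        for iv in tree[int(p)]:
            ci.append(i)
            gi.append(iv.data)
    return np.asarray(ci, dtype=np.int64), np.asarray(gi, dtype=np.int64)


def normalized_gene_contacts(
    contacts: pd.DataFrame,
    target_class: str,
    genes,
    L: int,
    min_background: int = MIN_BACKGROUND,
    min_distance: int = BACKGROUND_MIN_DISTANCE,
) -> pd.DataFrame:
    """Per-protein-coding-gene table of background-normalized target-RNA contacts.

    ``target_class`` is "rRNA" (pooling 16S, 23S and 5S molecules) or "6S".
    Columns: gene_id, length, target_count, background_count, ratio (NaN for
    excluded genes), activity, included.
    """
    if target_class == "rRNA":
        classes = RRNA_CLASSES
    elif target_class == "6S":
        classes = {"6S"}
    else:
        raise ValueError(f"unknown target class {target_class!r}")
    if L <= 2 * min_distance:
        raise ConfigurationError(
            f"genome length {L} leaves no region beyond {min_distance} bp"
        )
    if "gene_id" not in contacts:
        raise ValueError("contacts must be gene-assigned first")

    pc_genes = [g for g in genes if g.rna_class == "mRNA"]
    n = len(pc_genes)
    mids = np.array([gene_middle(g, L) for g in pc_genes])

    # target-RNA contacts anchored inside gene bodies
    tgt = contacts[contacts["rna_class"].isin(classes)]
    target_counts = np.zeros(n, dtype=np.int64)
    if len(tgt):
        _, gi = _pc_gene_of_anchor(tgt["dna_pos"].to_numpy(), pc_genes, L)
        np.add.at(target_counts, gi, 1)

    # distal-mRNA background: anchor in the body, source > min_distance from the middle
    mrna = contacts[(contacts["rna_class"] == "mRNA") & contacts["gene_id"].notna()]
    background = np.zeros(n, dtype=np.int64)
    if len(mrna):
        ci, gi = _pc_gene_of_anchor(mrna["dna_pos"].to_numpy(), pc_genes, L)
        src = mrna["rna3_pos"].to_numpy()[ci]
        far = np.asarray(circular_distance(src, mids[gi], L)) > min_distance
        np.add.at(background, gi[far], 1)

    # own-mRNA activity within +/-5 kb of the middle
    activity = np.zeros(n, dtype=np.int64)
    idx_of = {g.id: i for i, g in enumerate(pc_genes)}
    assigned = mrna[mrna["gene_id"].isin(idx_of)]
    if len(assigned):
        gi = assigned["gene_id"].map(idx_of).to_numpy(dtype=np.int64)
        d = np.asarray(circular_distance(assigned["dna_pos"].to_numpy(), mids[gi], L))
        np.add.at(activity, gi[d <= ACTIVITY_RADIUS], 1)

    included = background >= min_background
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(included, target_counts / np.maximum(background, 1), np.nan)
    return pd.DataFrame(
        {
            "gene_id": [g.id for g in pc_genes],
            "length": [g.span(L) for g in pc_genes],
            "target_count": target_counts,
            "background_count": background,
            "ratio": ratio,
            "activity": activity,
            "included": included,
        }
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int
    subset: str
    scale: str


def correlate_activity(
    x, y, subset: str = "all", scale: str = "log"
) -> CorrelationResult:
    """Pearson correlation and linear regression of y on x.

    ``subset="top10"`` restricts to the highest decile of x (the most active
    genes); ``scale="log"`` applies log10(v + 1) to both axes before fitting,
    with the raw scale available via ``scale="raw"``. Non-finite pairs are
    dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if subset == "top10":
        k = max(int(np.ceil(0.1 * len(x))), 0)
        order = np.argsort(x)[::-1][:k]
        x, y = x[order], y[order]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if scale == "log":
        x, y = np.log10(x + 1), np.log10(y + 1)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    if len(x) < 3:
        raise ValueError("insufficient data: need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), slope=float(reg.slope),
        intercept=float(reg.intercept), n=len(x), subset=subset, scale=scale,
    )


def correlate_with_expression(
    contacts: pd.DataFrame, expression: pd.Series, scale: str = "log"
) -> CorrelationResult:
    """Correlate per-mRNA genomic contact totals with an external expression table."""
    totals = (
        contacts[(contacts["rna_class"] == "mRNA") & contacts["gene_id"].notna()]
        .groupby("gene_id")
        .size()
    )
    common = totals.index.intersection(expression.index)
    return correlate_activity(
        expression.loc[common].to_numpy(), totals.loc[common].to_numpy(), scale=scale
    )
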