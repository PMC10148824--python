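"""Synthetic RNA-DNA proximity-ligation data with known ground truth.

The generator emulates the structure of a microbial RNA-DNA interactome on a
single circular replicon:

* an operonic annotation (protein-coding operons on both strands, one
  16S/23S/5S rRNA locus, tRNA genes, one 6S RNA gene) with a log-normal
  gene-length law (median 0.8 kb, the E. coli value);
* mRNA contacts concentrated at the encoding gene with a "polymerase drag"
  component: the nascent polycistronic transcript is carried by RNA polymerase
  from the fragment's encoding site to the end of its operon, so cis contacts
  fall preferentially downstream (in the transcription direction);
* rRNA contacts spread genome-wide with enrichment at transcriptionally
  active protein-coding genes (co-transcriptional translation), controlled by
  a coupling strength ``alpha``;
* 6S RNA contacts depleted from active genes (strength ``gamma``);
* tRNA contacts uniform along the genome;
* raw paired reads of the form ``[DNA 18-20 nt][bridge][RNA 3' cDNA]`` /
  ``[GGG][RNA 5' segment]`` with a truth sidecar keyed by read name.

DNA-portion anchors are snapped to NlaIII (CATG) sites by default
(``nlaiii_aware``), mirroring the restriction chemistry that places real
anchors at CATG junctions; the latent continuous contact model is available
with ``nlaiii_aware=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_genome import (
    Gene,
    Genome,
    Operon,
    RRNA_CLASSES,
    opposite_strand,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# An arbitrary fixed 30-mer used as the bridge; verified absent from every
# simulated genome. The real bridge sequence can be substituted via the config.
DEFAULT_BRIDGE = "GCTGAGGATCATTAGCTGCCGTACGGTCAA"
DEFAULT_SWITCH_OLIGO = "TACGTAGCTAGGCCA"


class PackingError(ValueError):
    """Requested annotation mass does not fit on the replicon."""


@dataclass
class SimulationConfig:
    """Parameters of the generative model; defaults are the study conditions.

    Lengths are base pairs. ``class_fractions`` gives the share of contacts per
    RNA class (mRNA / pooled rRNA / tRNA / 6S); they are realized exactly.
    """

    seed: int = 0
    L: int = 2_400_000
    n_operons: int = 300
    genes_per_operon_mean: float = 3.0  # geometric, support >= 1
    gene_length_median: float = 800.0  # log-normal median (E. coli: 0.8 kb)
    gene_length_sigma: float = 0.4
    expression_sigma: float = 1.0  # log-normal per operon
    activity_quantile: float = 0.95  # normalizer for alpha/gamma couplings
    n_contacts: int = 100_000
    class_fractions: dict = field(
        default_factory=lambda: {"mRNA": 0.60, "rRNA": 0.09, "tRNA": 0.21, "6S": 0.10}
    )
    p_cis: float = 0.7  # probability an mRNA contact is captured via the nascent transcript
    capture_scale: float = 200.0  # Laplace scale of local capture noise (bp)
    alpha: float = 0.5  # rRNA enrichment ~ 1 + alpha * activity
    gamma: float = 0.5  # 6S depletion ~ max(0, 1 - gamma * activity)
    nlaiii_aware: bool = True
    n_trna_genes: int = 20
    bridge_sequence: str = DEFAULT_BRIDGE
    ggg_tag: str = "GGG"
    switch_oligo: str = DEFAULT_SWITCH_OLIGO
    read_length: int = 100
    dna_fragment_range: tuple = (22, 24)  # genomic extent incl. the CATG end
    rna3_len_range: tuple = (20, 50)
    rna5_len_range: tuple = (25, 40)
    min_molecule: int = 30  # shortest sequenceable RNA fragment
    molecule_len_median: float = 150.0
    molecule_len_sigma: float = 0.5
    error_rate: float = 0.0
    artifact_fraction: float = 0.05  # template-switch artifacts among emitted reads

    def __post_init__(self):
        if not 0.0 <= self.p_cis <= 1.0:
            raise ValueError("p_cis must lie in [0, 1]")
        if not 0.0 <= self.gamma:
            raise ValueError("gamma must be non-negative")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["dna_fragment_range"] = list(d["dna_fragment_range"])
        d["rna3_len_range"] = list(d["rna3_len_range"])
        d["rna5_len_range"] = list(d["rna5_len_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("dna_fragment_range", "rna3_len_range", "rna5_len_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Annotation


def _random_sequence(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_annotation(config: SimulationConfig):
    """Draw a circular genome, its gene annotation, and its operon structure.

    Operons and standalone ncRNA loci are placed without overlap, separated by
    random intergenic gaps; genes tile each operon in transcription order.
    Raises :class:`PackingError` when the requested gene mass exceeds L.
    """
    rng = np.random.default_rng(config.seed)
    mu = np.log(config.gene_length_median)

    blocks = []  # (kind, payload, block_length)
    for i in range(config.n_operons):
        k = int(rng.geometric(1.0 / config.genes_per_operon_mean))
        lengths = np.maximum(
            60, rng.lognormal(mu, config.gene_length_sigma, size=k).astype(int)
        )
        gaps = rng.integers(10, 60, size=k)  # gap after each gene but the last
        gaps[-1] = 0
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append(("operon", (f"op{i:04d}", lengths, gaps, strand), int(lengths.sum() + gaps.sum())))

    rrna = [("rrn16S", 1542, "rRNA16S"), ("rrn23S", 2904, "rRNA23S"), ("rrn5S", 120, "rRNA5S")]
    blocks.append(("rrna_locus", rrna, sum(l for _, l, _ in rrna) + 50 * (len(rrna) - 1)))
    for t in range(config.n_trna_genes):
        blocks.append(("nc", (f"trna{t:02d}", 76, "tRNA"), 76))
    blocks.append(("nc", ("ssrS", 183, "6S"), 183))

    total = sum(b[2] for b in blocks)
    n_gaps = len(blocks) + 1
    if total + n_gaps > config.L:
        raise PackingError(
            f"annotation mass {total} bp (+{n_gaps} minimal gaps) exceeds L={config.L}"
        )
    slack = config.L - total - n_gaps
    gap_sizes = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps)) + 1

    order = rng.permutation(len(blocks))
    genes: list[Gene] = []
    operons: list[Operon] = []
    cursor = int(gap_sizes[0])
    for gi, bi in enumerate(order):
        kind, payload, blen = blocks[bi]
        if kind == "operon":
            oid, lengths, gaps, strand = payload
            gids, pos = [], cursor
            for j, (gl, gp) in enumerate(zip(lengths, gaps)):
                gid = f"{oid}_g{j}"
                genes.append(Gene(gid, pos, pos + int(gl), strand, "mRNA"))
                gids.append(gid)
                pos += int(gl) + int(gp)
            if strand == "-":
                gids = gids[::-1]  # transcription runs right-to-left
            operons.append(Operon(oid, tuple(gids), cursor, cursor + blen, strand))
        elif kind == "rrna_locus":
            pos = cursor
            for name, glen, cls in payload:
                genes.append(Gene(name, pos, pos + glen, "+", cls))
                pos += glen + 50
        else:
            name, glen, cls = payload
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(name, cursor, cursor + glen, strand, cls))
        cursor += blen + int(gap_sizes[gi + 1])

    seq = _random_sequence(rng, config.L)
    if config.bridge_sequence in seq or revcomp(config.bridge_sequence) in seq:
        raise RuntimeError("bridge sequence collides with the simulated genome")
    genome = Genome(name="synthetic_chr", length=config.L, sequence=seq)
    return genome, genes, operons


def simulate_expression(config: SimulationConfig, operons, genes) -> pd.Series:
    """Log-normal expression per operon, shared by member genes; ncRNA loci get
    their own draws. Indexed by gene_id."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    values = {}
    for op in operons:
        e = float(rng.lognormal(0.0, config.expression_sigma))
        for gid in op.gene_ids:
            values[gid] = e
    for g in genes:
        if g.id not in values:
            values[g.id] = float(rng.lognormal(0.0, config.expression_sigma))
    return pd.Series(values, name="expression")


# ---------------------------------------------------------------------------
# Contacts


def _catg_anchor_sites(genome: Genome):
    """Positions usable as DNA-portion anchors per strand.

    The anchor is the coordinate of the DNA-portion base adjoining the NlaIII
    junction. On the + strand the fragment ends with the CATG at [e-3, e]; on
    the - strand the (palindromic) site occupies [e, e+3].
    """
    seq = genome.sequence + genome.sequence[:3]
    starts = []
    i = seq.find("CATG")
    while i != -1:
        starts.append(i % genome.length)
        i = seq.find("CATG", i + 1)
    starts = np.unique(np.asarray(starts, dtype=np.int64))
    if starts.size == 0:
        raise ValueError("genome contains no CATG site; cannot snap anchors")
    plus = np.sort((starts + 3) % genome.length)
    minus = starts
    return {"+": plus, "-": minus}


def _snap_circular(pos: np.ndarray, sites: np.ndarray, L: int) -> np.ndarray:
    """Nearest site on the circle for each position (ties break to the left site)."""
    ext = np.concatenate([sites, sites[:1] + L])
    idx = np.searchsorted(ext, pos)
    lo = ext[np.maximum(idx - 1, 0)]
    lo = np.where(idx == 0, sites[-1] - L, lo)
    hi = ext[np.minimum(idx, ext.size - 1)]
    snapped = np.where(pos - lo <= hi - pos, lo, hi)
    return snapped % L


def _weighted_positions(rng, weights_cum, n: int) -> np.ndarray:
    u = rng.random(n) * weights_cum[-1]
    return np.searchsorted(weights_cum, u, side="right")


def _activity_weights(genes, expression, config) -> np.ndarray:
    """Normalized transcriptional activity per bp: expression / Q95, clipped to [0,1]."""
    act = np.zeros(config.L)
    pc = [g for g in genes if g.rna_class == "mRNA"]
    if not pc:
        return act
    vals = np.array([expression[g.id] for g in pc])
    denom = np.quantile(vals, config.activity_quantile)
    for g, v in zip(pc, vals):
        act[g.start : g.end] = min(v / denom, 1.0)
    return act


def simulate_contacts(
    config: SimulationConfig,
    genome: Genome,
    genes,
    operons,
    expression: pd.Series | None = None,
    seed: int | None = None,
    nlaiii_aware: bool | None = None,
) -> pd.DataFrame:
    """Draw the ground-truth contact table.

    mRNA contacts: with probability ``p_cis`` the RNA-fragment 3' end ``r`` is
    sampled within the encoding gene, the polymerase position uniformly on the
    transcribed path from ``r`` to the operon end (downstream drag), and the
    DNA anchor at the polymerase position plus Laplace(0, capture_scale) noise;
    otherwise the anchor is uniform on the genome. rRNA anchors follow density
    1 + alpha*activity, 6S follows max(0, 1 - gamma*activity), tRNA is uniform.
    Per-RNA contact counts are proportional to expression; the RNA 3' portion
    strand is always opposite to the source-gene strand.
    """
    if expression is None:
        expression = simulate_expression(config, operons, genes)
    if nlaiii_aware is None:
        nlaiii_aware = config.nlaiii_aware
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 2])
    )
    L = config.L
    min_up = config.min_molecule - 1  # transcript bases required 5' of the 3' end

    # exact per-class counts (largest remainder)
    names = list(config.class_fractions)
    raw = np.array([config.class_fractions[c] for c in names]) * config.n_contacts
    counts = np.floor(raw).astype(int)
    rem = config.n_contacts - counts.sum()
    counts[np.argsort(raw - np.floor(raw))[::-1][:rem]] += 1
    n_by_class = dict(zip(names, counts))

    gene_by_id = {g.id: g for g in genes}
    op_of_gene = {}
    for op in operons:
        for gid in op.gene_ids:
            op_of_gene[gid] = op

    act = _activity_weights(genes, expression, config)
    frames = []

    # --- mRNA ---------------------------------------------------------------
    n_mrna = n_by_class.get("mRNA", 0)
    pc_genes = [g for g in genes if g.rna_class == "mRNA" and g.id in op_of_gene]
    if n_mrna and pc_genes:
        w = np.array([expression[g.id] for g in pc_genes], float)
        pick = rng.choice(len(pc_genes), size=n_mrna, p=w / w.sum())
        gstart = np.array([g.start for g in pc_genes])[pick]
        gend = np.array([g.end for g in pc_genes])[pick]
        strand_plus = np.array([g.strand == "+" for g in pc_genes])[pick]
        ops = [op_of_gene[pc_genes[i].id] for i in pick]
        op_start = np.array([o.start for o in ops])
        op_end = np.array([o.end for o in ops])

        # 3' end r within the gene, leaving >= min_molecule of transcript upstream
        lo = np.where(strand_plus, np.maximum(gstart, op_start + min_up), gstart)
        hi = np.where(strand_plus, gend, np.minimum(gend, op_end - min_up))
        hi = np.maximum(hi, lo + 1)
        r = lo + (rng.random(n_mrna) * (hi - lo)).astype(int)

        cis = rng.random(n_mrna) < config.p_cis
        # polymerase drawn on the transcribed path from r to the operon end
        pol_plus = r + (rng.random(n_mrna) * (op_end - r)).astype(int)
        pol_minus = op_start + (rng.random(n_mrna) * (r - op_start + 1)).astype(int)
        pol = np.where(strand_plus, pol_plus, pol_minus)
        noise = np.round(rng.laplace(0.0, config.capture_scale, n_mrna)).astype(int) \
            if config.capture_scale > 0 else 0
        dna_cis = (pol + noise) % L
        dna_trans = rng.integers(0, L, size=n_mrna)
        dna = np.where(cis, dna_cis, dna_trans)

        frames.append(
            pd.DataFrame(
                {
                    "rna_class": "mRNA",
                    "source_gene_id": [pc_genes[i].id for i in pick],
                    "rna3_pos": r,
                    "rna_strand": np.where(strand_plus, "-", "+"),
                    "dna_pos": dna,
                    "tx_start": op_start,
                    "tx_end": op_end,
                    "cis": cis,
                }
            )
        )

    # --- noncoding classes ----------------------------------------------------
    def nc_frame(cls_name, members, n, weight_profile):
        if n == 0 or not members:
            return None
        lens = np.array([g.span(L) for g in members], float)
        pick = rng.choice(len(members), size=n, p=lens / lens.sum())
        gstart = np.array([g.start for g in members])[pick]
        gend = np.array([g.end for g in members])[pick]
        strand_plus = np.array([g.strand == "+" for g in members])[pick]
        lo = np.where(strand_plus, gstart + min_up, gstart)
        hi = np.where(strand_plus, gend, gend - min_up)
        hi = np.maximum(hi, lo + 1)
        lo = np.minimum(lo, hi - 1)
        r = lo + (rng.random(n) * (hi - lo)).astype(int)
        if weight_profile is None:
            dna = rng.integers(0, L, size=n)
        else:
            cum = np.cumsum(weight_profile)
            dna = _weighted_positions(rng, cum, n)
        return pd.DataFrame(
            {
                "rna_class": [members[i].rna_class for i in pick],
                "source_gene_id": [members[i].id for i in pick],
                "rna3_pos": r,
                "rna_strand": np.where(strand_plus, "-", "+"),
                "dna_pos": dna,
                "tx_start": gstart,
                "tx_end": gend,
                "cis": False,
            }
        )

    rrna_genes = [g for g in genes if g.rna_class in RRNA_CLASSES]
    trna_genes = [g for g in genes if g.rna_class == "tRNA"]
    sixs_genes = [g for g in genes if g.rna_class == "6S"]
    rrna_w = 1.0 + config.alpha * act if config.alpha > 0 else None
    sixs_w = np.maximum(0.0, 1.0 - config.gamma * act) if config.gamma > 0 else None
    for f in (
        nc_frame("rRNA", rrna_genes, n_by_class.get("rRNA", 0), rrna_w),
        nc_frame("tRNA", trna_genes, n_by_class.get("tRNA", 0), None),
        nc_frame("6S", sixs_genes, n_by_class.get("6S", 0), sixs_w),
    ):
        if f is not None:
            frames.append(f)

    truth = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["rna_class", "source_gene_id", "rna3_pos", "rna_strand",
                 "dna_pos", "tx_start", "tx_end", "cis"]
    )
    truth["dna_strand"] = np.where(rng.random(len(truth)) < 0.5, "+", "-")
    if nlaiii_aware and len(truth):
        sites = _catg_anchor_sites(genome)
        pos = truth["dna_pos"].to_numpy()
        for s in ("+", "-"):
            m = (truth["dna_strand"] == s).to_numpy()
            pos[m] = _snap_circular(pos[m], sites[s], L)
        truth["dna_pos"] = pos
    truth.insert(0, "contact_id", np.arange(len(truth)))
    return truth


# ---------------------------------------------------------------------------
# Reads


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        arr[hit] = alphabet[rng.integers(0, 4, hit.size)]
    return arr.tobytes().decode()


def emit_reads(
    truth: pd.DataFrame,
    genome: Genome,
    config: SimulationConfig,
    fastq_fwd,
    fastq_rev,
    sidecar,
    seed: int | None = None,
) -> None:
    """Write the paired FASTQ files and the truth sidecar TSV for a contact table.

    Forward read: genomic DNA fragment ending at the anchor with its terminal
    CATG removed (18-20 nt), the bridge, then the cDNA of the RNA fragment's
    3' end; when the insert is short the template-switch trace (CCC + switch
    oligo) follows. Reverse read: GGG then the RNA fragment's 5' segment in
    sense orientation, placed on the same transcript so that valid pairs pass
    the proximity/strand filter; a configurable fraction of pairs instead
    violates it (template-switch artifacts), labelled in the sidecar.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 3])
    )
    L = genome.length
    dseq = genome.sequence + genome.sequence[:600]  # wrap-around slices
    bridge = config.bridge_sequence
    tag = "CCC" + config.switch_oligo

    def gslice(a, b):  # [a, b) with wrap
        a %= L
        return dseq[a : a + (b - a)]

    if truth["dna_pos"].max() >= L if len(truth) else False:
        raise ValueError("truth coordinates outside genome")

    n = len(truth)
    artifact = np.full(n, "none", dtype=object)
    if config.artifact_fraction > 0 and n:
        bad = rng.random(n) < config.artifact_fraction
        kind = rng.random(n) < 0.5
        artifact[bad & kind] = "far"
        artifact[bad & ~kind] = "same_strand"

    fq1, fq2, side_rows = [], [], []
    cols = truth[["contact_id", "rna_class", "source_gene_id", "rna3_pos",
                  "rna_strand", "dna_pos", "dna_strand", "tx_start", "tx_end"]]
    for i, row in enumerate(cols.itertuples(index=False)):
        m = int(rng.integers(config.dna_fragment_range[0], config.dna_fragment_range[1] + 1))
        if row.dna_strand == "+":
            frag = gslice(row.dna_pos - m + 1, row.dna_pos + 1)
        else:
            frag = revcomp(gslice(row.dna_pos, row.dna_pos + m))
        dna_part = frag[:-4]  # the CATG adjoining the bridge is absent from the read

        gene_plus = row.rna_strand == "-"  # RNA 3' portion maps opposite the gene
        r = row.rna3_pos
        avail = (r - row.tx_start + 1) if gene_plus else (row.tx_end - r)
        ml = int(
            np.clip(
                rng.lognormal(np.log(config.molecule_len_median), config.molecule_len_sigma),
                config.min_molecule,
                max(config.min_molecule, avail),
            )
        )
        cap3 = config.read_length - len(dna_part) - len(bridge)
        l3 = int(min(rng.integers(*config.rna3_len_range), ml, cap3))
        l5 = int(min(rng.integers(*config.rna5_len_range), ml))
        if gene_plus:
            rna3 = revcomp(gslice(r - l3 + 1, r + 1))
            u = r - ml + 1
            rna5 = gslice(u, u + l5)
        else:
            rna3 = gslice(r, r + l3)
            v = r + ml - 1
            rna5 = revcomp(gslice(v - l5 + 1, v + 1))

        if artifact[i] == "far":
            off = int(rng.integers(12_000, 50_000))
            far = (r + off) % L
            rna5 = gslice(far, far + l5) if gene_plus else revcomp(gslice(far - l5 + 1, far + 1))
        elif artifact[i] == "same_strand":
            rna5 = revcomp(rna5)

        fwd = dna_part + bridge + rna3
        room = config.read_length - len(fwd)
        if room >= len(tag):  # template-switch read-through trace
            fwd = (fwd + tag + "A" * room)[: config.read_length]
        rev = config.ggg_tag + rna5
        fwd = _mutate(rng, fwd, config.error_rate)
        rev = _mutate(rng, rev, config.error_rate)

        name = f"sim{row.contact_id}"
        fq1.append(f"@{name}\n{fwd}\n+\n{'I' * len(fwd)}\n")
        fq2.append(f"@{name}\n{rev}\n+\n{'I' * len(rev)}\n")
        side_rows.append(
            (name, row.contact_id, row.rna_class, row.source_gene_id, row.rna3_pos,
             row.rna_strand, row.dna_pos, row.dna_strand, artifact[i])
        )

    Path(fastq_fwd).write_text("".join(fq1))
    Path(fastq_rev).write_text("".join(fq2))
    pd.DataFrame(
        side_rows,
        columns=["read_id", "contact_id", "rna_class", "source_gene_id", "rna3_pos",
                 "rna_strand", "dna_pos", "dna_strand", "artifact"],
    ).to_csv(sidecar, sep="\t", index=False)


def simulate_dataset(config: SimulationConfig, outdir, prefix="sim"):
    """Convenience driver: annotation + expression + contacts + reads on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, operons = simulate_annotation(config)
    expression = simulate_expression(config, operons, genes)
    truth = simulate_contacts(config, genome, genes, operons, expression)
    from .core_genome import write_annotation_gff, write_genome, write_operons_tsv

    write_genome(genome, outdir / f"{prefix}_genome.fasta")
    write_annotation_gff(genes, operons, genome, outdir / f"{prefix}_annotation.gff3")
    write_operons_tsv(operons, outdir / f"{prefix}_operons.tsv")
    truth.to_csv(outdir / f"{prefix}_truth.tsv", sep="\t", index=False)
    emit_reads(
        truth, genome, config,
        outdir / f"{prefix}_R1.fastq", outdir / f"{prefix}_R2.fastq",
        outdir / f"{prefix}_sidecar.tsv",
    )
    return genome, genes, operons, expression, truth
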