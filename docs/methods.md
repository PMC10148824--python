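# Methods

## Scope and data model

`redcmicro` analyses RNA–DNA proximity-ligation data on a **single circular
replicon**. Internally all coordinates are 0-based half-open and every
positional computation is modular in the genome length L; multi-replicon
input is rejected explicitly rather than silently mishandled. Genes carry a
strand and an RNA class (`mRNA`, `rRNA16S/23S/5S`, `tRNA`, `6S`, `other`);
operons are ordered gene lists on one strand and must be *supplied* (GFF3
`operon` features or a sidecar TSV) — the package deliberately does no operon
prediction, since operon definitions are an input, not an inference, of this
analysis.

The circular distance between two coordinates is min(d₁, d₂) with
d₁ = |a − b| and d₂ = |d₁ − L|, i.e. the shorter arc; gene middles use
floor((start + end)/2) (modular for wrap-around genes), so interval
membership is deterministic on ties.

## Read anatomy and the filtering cascade

A contact chimera reads as `[DNA 18–20 nt][bridge][cDNA of the RNA fragment's
3′ end]` (forward) and `[GGG][RNA fragment's 5′ segment, sense
orientation]` (reverse). The cascade:

1. **Scan** for the first bridge occurrence (exact by default; ≤1 mismatch
   optional, first occurrence wins) and the first GGG on the reverse read.
   The RNA 3′ portion is truncated at the template-switch trace. With no
   further information that trace is the literal `CCC` left by the
   switch-oligo rGrGrG (the default `trim_tag`); when the switch-oligo
   sequence is configured, trimming instead anchors on `CCC` + the oligo's
   prefix. The distinction matters: a bare C-triplet occurs every ~64 bp in
   transcribed sequence, so bare-CCC trimming truncates a double-digit
   percentage of genuine RNA portions below the 10-nt minimum, whereas the
   anchored tag is effectively unambiguous. `process_run` uses the anchored
   form whenever the switch oligo is known.
2. **Length filter**: DNA portion 18–20 nt, RNA portions ≥ 10 nt.
3. **CATG reattachment**: the NlaIII overhang lost during library prep is
   re-appended to the bridge-adjoining end of the DNA portion (18–20 →
   22–24 nt), restoring the original genomic sequence and improving
   mappability.
4. **Mapping**: each portion is mapped independently by an exact-match
   occurrence counter over both strands (seed k-mer = 10 nt, the minimum
   portion length, then direct verification; wrap-around matches across the
   origin are supported). `unique` means exactly one occurrence counting
   both strands. This mapper is exact and adequate for synthetic genomes;
   for real libraries, externally produced SAM alignments can be ingested
   (`contacts_from_sam`) so any spliced/mismatch-aware aligner can stand in
   front of the same downstream machinery.
5. **Triple filter**: all three portions unique; RNA 3′ and 5′ portions
   within 10 kb (circular distance — the conservative reading on a circle)
   and on opposite strands. Rejections carry reason codes
   (`no_bridge`, `no_ggg`, `dna_length`, `rna_short`, `not_unique`,
   `far_apart`, `same_strand`) and the per-step survival counts are monotone
   non-increasing by construction.

Anchors: the DNA anchor is the coordinate of the DNA-portion base adjoining
the NlaIII site (the read's last DNA base); the RNA anchor is the mapped
coordinate of the RNA fragment's 3′ end (the read's first base after the
bridge). A contact is assigned to a gene when the RNA 3′ anchor falls in the
gene body and the RNA strand is the *complement* of the gene strand;
ambiguous overlaps (two qualifying genes) are dropped rather than
multi-counted.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the analyses.

* **Annotation**: L = 2.4 Mb; 300 protein-coding operons with geometric gene
  counts (mean 3) placed without overlap on both strands; gene lengths
  log-normal with median 800 bp (the E. coli median) and σ = 0.4; one
  16S/23S/5S rRNA locus (single copy, so rRNA portions map uniquely), 20
  tRNA genes, one 6S gene; random sequence. Per-operon expression is
  log-normal (σ = 1), shared by member genes (polycistronic).
* **mRNA contacts** (60%): source gene drawn ∝ expression. With probability
  p_cis = 0.7 the fragment's 3′ end r is uniform in the gene, the polymerase
  position uniform on the transcribed path from r to the operon end
  (**downstream drag** — the simplest model of a nascent transcript carried
  to the operon end, no premature termination), and the DNA anchor is the
  polymerase position plus Laplace(0, λ = 200 bp) capture noise; otherwise
  the anchor is uniform (trans background).
* **rRNA** (9%, the E. coli unique-contact share): anchors with density
  1 + α·activity; **tRNA** (21%): uniform; **6S** (10%): density
  max(0, 1 − γ·activity). Normalized activity is expression divided by the
  Q95 of protein-coding expression, clipped to [0,1] — max-normalization
  would make typical activities ~0.05 under a log-normal law and render the
  couplings vacuous. Defaults α = γ = 0.5. Class counts are realized
  exactly; per-RNA counts are proportional to expression in expectation.
* **NlaIII-aware anchors (default on)**: sampled anchors snap to the nearest
  position whose adjoining genomic 4-mer is CATG (the site is palindromic,
  so both strands use the same site set). This mirrors the restriction
  chemistry — real anchors sit at NlaIII junctions, which is also why real
  maps show NlaIII-dependent vertical striping — and makes CATG
  reattachment exactly consistent with the genome. In a uniform-random
  genome sites occur every ~256 bp, so snapping adds ≤ ~128 bp of jitter,
  negligible at the analysis resolutions. Statistical tests of the *latent*
  contact model (uniform nulls, KS tests, the pure-drag construction) set
  `nlaiii_aware=False` to sample the continuous model directly.
* **Reads**: the RNA fragment ("molecule") is log-normal (median 150 nt)
  clipped to the transcript; its 3′ end is drawn at least 30 nt into the
  transcript so both RNA portions can satisfy the 10-nt minimum — fragments
  with shorter 3′ overhangs are unsequenceable by construction, and
  excluding them costs 29 bp of positional resolution out of ~800. The RNA
  5′ segment sits on the same molecule, hence always within 10 kb of the 3′
  end; a configurable artifact fraction (default 5%) instead violates the
  proximity or strand rule to exercise the template-switch filter, labelled
  in the truth sidecar. When the insert is short the forward read carries
  the read-through trace `CCC + switch oligo`. Substitution errors at a
  configurable rate (default 0); base qualities are constant because the
  pipeline never uses them. Same seed ⇒ byte-identical FASTQ.

What the generator does **not** emulate: PCR duplicates, quality profiles,
indels, repeat families beyond the single rRNA locus (multi-copy rRNA
operons, the cause of the real-data rRNA mappability gap, can be constructed
explicitly in tests), expression-coupled RNA degradation, and genome
composition bias. Passing tests therefore demonstrate correctness of the
*computations* under a clean generative model, not robustness to every
artifact of real libraries.

## Analyses

* **Interval preference**: intervals are measured from the gene middle with
  half-open edges on circular distance — [0, 5 kb), [5, 50 kb), [50,
  500 kb), [500 kb, L/2]; the two flanks are pooled for the middle rings
  (the canonical edges require L > 1 Mb). Relative frequency =
  (count/length) / (total/L), so the length-weighted mean of the four
  relative frequencies is exactly 1. A mask (e.g. poorly mappable rRNA
  operons) removes contacts and the corresponding interval length; the
  normalization identity then holds on the unmasked remainder. The paper's
  robustness filter (≥ 500 contacts per RNA) is the default; desk-scale
  runs at 10⁵ contacts leave no single mRNA above 500, so the analysis
  drivers scale the filter to 100 — the filter is a depth-relative
  robustness device, not a biological constant.
* **Up/down profile**: the case table over sign(rna − dna) and d₁ vs d₂
  assigns each proper-strand mRNA contact upstream or downstream of its
  3′-end coordinate in the transcription direction; rna = dna ties get
  distance 0, the downstream convention of the far branch, and a flag (and
  can be excluded). Distances fall into exponential bins [0,64), [64,128),
  … clipped at L/2; frequencies are counts per bp of bin width. An
  exhaustive oracle test walks every coordinate pair on circles up to
  L = 500.
* **Cumulative operon maps**: window = operon ± half-operon-length flanks,
  24 equal bins (with half-operon flanks, "12 operon bins + 6 + 6 flank
  bins of equal width" and "window/24" coincide); matrices summed per
  orientation in genomic (unflipped) orientation, so sense triangles sit
  above and antisense triangles below the diagonal.
* **Normalization**: target counts are DNA anchors strictly inside the gene
  body [start, end); background counts are mRNA contacts in the body whose
  3′-end maps > 250 kb (circular, to the gene middle — the middle for
  consistency with every other middle-anchored measure) away; genes with
  background < 10 are excluded; activity uses a closed ±5 kb edge.
  Correlations are computed on log10(x+1) scale by default (raw available),
  with the top-10% subset taken as the highest-activity decile;
  the regression is reported alongside r and p.

## Numerical and design choices

* Contact matrices are scipy.sparse CSR — a 2.4 Mb genome at 100 bp
  resolution is a 24,000² matrix, far too large dense — with a bit-exact
  sparse-triplet TSV round trip. Replicate similarity is the Pearson
  correlation over all cells computed from sparse moments; merging with an
  empty (constant) map reports NaN similarity rather than failing.
* Replicate-similarity checks at simulated depth use 10 kb bins: at 10⁵
  contacts the 100 bp map is almost everywhere 0/1 and per-cell correlation
  is dominated by shot noise.
* The uniform-null check of the up/down ratios runs on a small circle
  (L = 4000) so that *every* exponential bin is well populated at 10⁵
  contacts; on the 2.4 Mb circle the [0,64) bin would hold ~3 contacts and
  a ratio test would be meaningless. A non-power-of-two L avoids a
  degenerate 1-bp terminal bin at exactly L/2.
* "Beyond the operon scale" in drag-recovery checks means bins wholly above
  the *maximum realized* operon span (ratios ≈ 1 there); bins below the
  *median* span must show ratio > 1. Bins in between are genuinely
  intermediate — the long-operon tail still drags there.
* Coupling-recovery experiments run at 3,000 protein-coding genes and 10⁶
  contacts on a 6 Mb replicon (3,000 genes of median 0.8 kb cannot pack
  into 2.4 Mb); this is the scale at which the ≥10-background filter keeps
  ~90% of genes.

## Known limitations

* The exact-match mapper has no mismatch tolerance; reads with sequencing
  errors in any portion are dropped rather than rescued (the SAM ingestion
  path exists for real data).
* Interval-ring lengths use the nominal continuous values (10 kb, 90 kb, …);
  the discrete rings differ by ±1 bp, invisible at analysis scale but worth
  knowing for exact accounting on tiny toy circles.
* Only substitution errors are simulated; indels would shift portion
  offsets and are not modelled.
* The 6S depletion model floors at zero density; very strong γ with highly
  expressed genes saturates rather than going negative, so the recoverable
  correlation magnitude plateaus.
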