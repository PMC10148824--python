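# redcmicro

Analysis of RNA–DNA proximity-ligation (RedC-style) data for single circular
prokaryotic replicons: from raw bridge-containing read pairs to whole-genome
RNA–DNA contact maps, cis/trans interval preferences, nascent-transcript
upstream/downstream profiles, cumulative operon maps, and
background-normalized noncoding-RNA contact statistics. A ground-truth
synthetic-data generator makes every stage testable end to end without
sequencing data.

## Who this is for

Groups applying RNA–DNA proximity ligation (RedC, GRID-seq, RADICL-seq-like
chemistry) to bacteria or archaea, where the chromosome is circular, genes are
organized in polycistronic operons, and the interesting signals are:

* mRNAs held near their encoding genes by the transcription machinery, with a
  *downstream* bias — a nascent polycistronic transcript is carried by RNA
  polymerase to the end of its operon;
* rRNA spread genome-wide but enriched at transcriptionally active
  protein-coding genes (co-transcriptional translation);
* 6S RNA, the σ70 repressor, depleted from active genes.

## The method in brief

Each sequenced chimera is `[DNA 18–20 nt][bridge][RNA 3′ cDNA]` on the forward
read and `[GGG][RNA 5′ segment]` on the reverse read. The pipeline scans for
the bridge and the GGG tag, extracts the three portions, re-appends the CATG
lost at the NlaIII junction to the DNA portion (18–20 → 22–24 nt), maps all
three portions independently, keeps only triples that map uniquely, and
discards template-switch artifacts (RNA 3′/5′ portions > 10 kb apart on the
circle, or on the same strand). The RNA 3′ portion must map to the strand
*opposite* its gene — that is how a contact is assigned to its source RNA.

All coordinate arithmetic is modular. For positions *rna* and *dna* on a
circle of length *L*, the contact distance is min(d₁, d₂) with
d₁ = |rna − dna|, d₂ = |d₁ − L|; the side (upstream/downstream of the RNA 3′
end with respect to transcription) follows the full case table over the sign
of rna − dna and the d₁/d₂ comparison.

Key statistics:

* **Interval preference** — per RNA, contact frequencies in ±5 kb, 5–50 kb,
  50–500 kb and >500 kb of the encoding gene's middle, each divided by the
  RNA's genome-average contact frequency (total/L). A per-locus mask supports
  the flank-only variant used when parental-locus mappability is poor.
* **Up/down profile** — upstream vs downstream contact frequencies in
  exponential distance bins [0,64), [64,128), [128,256), …; the
  downstream/upstream ratio > 1 at operon scale is the polymerase-drag
  signature.
* **Cumulative operon maps** — each operon ± half-operon-length flanks split
  into 24 bins; the summed 24×24 matrices show triangles above the diagonal
  for sense operons and below for antisense operons.
* **Background normalization** — a gene's rRNA (pooled 16S/23S/5S) or 6S
  contacts divided by its contacts with mRNA fragments transcribed > 250 kb
  away, cancelling gene length, cross-linking, digestion and mappability
  biases; genes with < 10 background contacts are excluded. Gene activity is
  the gene's own-mRNA contacts within ±5 kb of its middle.

## Worked example

```bash
python analysis/01_simulate_dataset.py        # genome + annotation + reads
python analysis/02_process_reads.py           # filtering cascade + recovery
python analysis/03_contact_maps_and_intervals.py
python analysis/04_mrna_positional_analysis.py
python analysis/05_ncrna_normalization.py
```

On the default 2.4 Mb replicon (300 operons, 10⁵ contacts, seed 3) this
prints, among other things:

```
exact recovery of valid truth contacts: 100.00%
replicate correlation at 10 kb bins: Pearson r = 0.994

median relative contact frequency per interval (by RNA class):
           relfreq_I1  relfreq_I2  relfreq_I3  relfreq_I4
6S               1.06        0.98        1.00        1.00
mRNA           166.85        0.34        0.30        0.30
rRNA             0.91        1.01        1.00        1.00
tRNA             0.98        1.06        1.01        0.99

sense operons (n=154): 89.7% of off-diagonal mass above the diagonal
antisense operons (n=146): 7.9% of off-diagonal mass above the diagonal

rRNA:  all genes: Pearson r = +0.278   (activity coupling recovered)
6S:    all genes: Pearson r = -0.350   (depletion from active genes)
```

Read it as: mRNAs contact their parental interval ~170× more often than the
genome average while tRNA/rRNA/6S profiles are flat; the downstream/upstream
ratio starts near 1.2 in the [0,64) bin, peaks at operon scale and decays to
1 beyond the longest operons; rRNA contact ratios rise with gene activity and
6S ratios fall with it.

## Layout

```
src/redcmicro/    core_genome, synthetic_data, read_processing,
                  contacts, profiles, normalization
analysis/         numbered narrative drivers (write to results/ and scratch/)
tests/            pytest suite, including end-to-end acceptance checks
docs/methods.md   model, parameters, assumptions, limitations
```
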