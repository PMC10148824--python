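"""Build binned RNA-DNA contact maps, merge pseudo-replicates, and compute the
four-interval cis/trans preference table.

Uses the recovered contacts from 02_process_reads.py (falls back to the truth
table when the pipeline has not been run). Writes the sparse map, the
replicate correlation and the per-RNA interval table under results/; a
coarse heatmap goes to scratch/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from redcmicro.contacts import assign_rna_to_genes, build_contact_map, merge_replicates
from redcmicro.core_genome import load_annotation, load_genome
from redcmicro.profiles import interval_preference_table
from redcmicro.synthetic_data import SimulationConfig, simulate_contacts

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=ROOT / "scratch" / "sim")
    ap.add_argument("--bin-size", type=int, default=100)
    ap.add_argument("--min-contacts", type=int, default=100,
                    help="per-RNA contact filter, scaled to simulated depth")
    args = ap.parse_args()

    cfg = SimulationConfig.from_yaml(args.datadir / "config.yaml")
    genome = load_genome(args.datadir / "sim_genome.fasta")
    genes, operons = load_annotation(
        args.datadir / "sim_annotation.gff3", genome,
        operon_tsv=args.datadir / "sim_operons.tsv",
    )
    contacts_path = args.datadir / "sim_contacts.tsv"
    if contacts_path.exists():
        raw = pd.read_csv(contacts_path, sep="\t")
    else:
        raw = pd.read_csv(args.datadir / "sim_truth.tsv", sep="\t").rename(
            columns={"rna_strand": "rna3_strand"}
        )
    contacts = assign_rna_to_genes(raw, genes, genome.length)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    cmap = build_contact_map(contacts, L=genome.length, bin_size=args.bin_size)
    cmap.to_tsv(results / "contact_map_triplets.tsv")
    print(f"contact map: {cmap.n_bins} x {cmap.n_bins} bins at {args.bin_size} bp, "
          f"{cmap.total()} contacts")

    # pseudo-replicate: an independent contact draw from the same model
    rep = simulate_contacts(
        cfg, genome, genes, operons, seed=cfg.seed + 1
    )
    ma = build_contact_map(contacts, L=genome.length, bin_size=10_000)
    mb = build_contact_map(rep, L=genome.length, bin_size=10_000)
    _, r = merge_replicates(ma, mb)
    print(f"replicate correlation at 10 kb bins: Pearson r = {r:.3f}")

    tab = interval_preference_table(
        contacts, genes, genome.length, min_contacts=args.min_contacts
    )
    tab.to_csv(results / "interval_preferences.tsv", sep="\t", index=False)
    cls = tab.groupby(tab["rna_class"].map(
        lambda c: "rRNA" if c.startswith("rRNA") else c
    ))[["relfreq_I1", "relfreq_I2", "relfreq_I3", "relfreq_I4"]].median()
    print("\nmedian relative contact frequency per interval (by RNA class):")
    print(cls.round(2).to_string())

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        coarse = build_contact_map(contacts, L=genome.length, bin_size=10_000)
        fig, ax = plt.subplots(figsize=(6, 5))
        with np.errstate(divide="ignore"):
            ax.imshow(np.log10(coarse.counts.toarray() + 1), cmap="Reds", origin="lower")
        ax.set_xlabel("DNA bin (10 kb)")
        ax.set_ylabel("RNA source bin (10 kb)")
        (ROOT / "scratch").mkdir(exist_ok=True)
        fig.savefig(ROOT / "scratch" / "contact_map.png", dpi=150)
        print("\nheatmap: scratch/contact_map.png")
    except Exception as e:  # plotting is optional
        print(f"(skipped heatmap: {e})")


if __name__ == "__main__":
    main()
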