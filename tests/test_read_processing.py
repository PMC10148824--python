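import numpy as np
import pandas as pd
import pytest

from redcmicro.core_genome import Genome
from redcmicro.read_processing import (
    GenomeIndex,
    MappedTriple,
    MapResult,
    filter_triple,
    map_portion,
    process_run,
    reattach_catg,
    scan_read_pair,
)
from redcmicro.synthetic_data import emit_reads, revcomp

BRIDGE = "GCTGAGGATCATTAGCTGCCGTACGGTCAA"


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def random_seq_no_ccc(rng, n):
    while True:
        s = random_seq(rng, n)
        if "CCC" not in s:
            return s


class TestScan:
    def test_splits_pair_into_three_portions(self):
        rng = np.random.default_rng(0)
        dna = random_seq(rng, 19)
        rna3, rna5 = random_seq_no_ccc(rng, 40), random_seq(rng, 35)
        res = scan_read_pair(dna + BRIDGE + rna3, "GGG" + rna5, BRIDGE)
        assert (res.dna_seq, res.rna3_seq, res.rna5_seq) == (dna, rna3, rna5)
        assert res.rna3_offset == 19 + len(BRIDGE)

    def test_missing_bridge_is_a_rejection_not_an_error(self):
        assert scan_read_pair("ACGT" * 20, "GGGACGT", BRIDGE) == "no_bridge"

    def test_missing_ggg_rejected(self):
        assert scan_read_pair("A" * 19 + BRIDGE + "T" * 20, "ATATAT", BRIDGE) == "no_ggg"

    def test_rna3_truncated_at_first_ccc(self):
        # string-scan oracle: everything between bridge end and first CCC
        fwd = "A" * 19 + BRIDGE + "ATGATGATGATG" + "CCC" + "T" * 20
        expected = fwd[19 + len(BRIDGE):].split("CCC")[0]
        res = scan_read_pair(fwd, "GGGACGTACGTT", BRIDGE)
        assert res.rna3_seq == expected
        assert len(res.rna3_seq) == 12

    def test_one_mismatch_bridge_found_when_allowed(self):
        bad = "T" + BRIDGE[1:]
        fwd = "A" * 18 + bad + "G" * 20
        assert scan_read_pair(fwd, "GGGAAAA", BRIDGE) == "no_bridge"
        res = scan_read_pair(fwd, "GGGAAAA", BRIDGE, max_mismatch=1)
        assert res.dna_seq == "A" * 18

    def test_switch_anchored_trim_tag_ignores_genomic_ccc(self):
        rna3 = "ATGCCCTTAGGA"  # genomic CCC inside the transcript
        fwd = "A" * 19 + BRIDGE + rna3 + "CCCTACGTA"
        res = scan_read_pair(fwd, "GGGAAAA", BRIDGE, trim_tag="CCCTACGTA")
        assert res.rna3_seq == rna3


class TestReattachCatg:
    @pytest.mark.parametrize("n,expected", [(18, 22), (19, 23), (20, 24)])
    def test_extends_by_four(self, n, expected):
        out = reattach_catg("A" * n)
        assert len(out) == expected
        assert out.endswith("CATG")

    @pytest.mark.parametrize("n", [17, 21, 0])
    def test_out_of_range_length_rejected(self, n):
        with pytest.raises(ValueError):
            reattach_catg("A" * n)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(42)
    return Genome("t", 20_000, sequence=random_seq(rng, 20_000))


@pytest.fixture(scope="module")
def index(genome):
    return GenomeIndex(genome)


class TestMapper:
    def test_forward_read_maps_uniquely_to_its_origin(self, genome, index):
        seq = genome.sequence[5_000:5_025]
        res = map_portion(seq, index)
        assert (res.status, res.pos, res.strand) == ("unique", 5_000, "+")

    def test_reverse_complement_maps_to_minus_strand_same_coordinate(self, genome, index):
        seq = revcomp(genome.sequence[5_000:5_025])
        res = map_portion(seq, index)
        assert (res.status, res.pos, res.strand) == ("unique", 5_000, "-")

    def test_wraparound_origin_read_maps(self, genome, index):
        seq = genome.sequence[-10:] + genome.sequence[:15]
        res = map_portion(seq, index)
        assert (res.status, res.pos) == ("unique", genome.length - 10)

    def test_duplicated_locus_is_multi(self):
        rng = np.random.default_rng(1)
        core = random_seq(rng, 2_000)
        dup = random_seq(rng, 300)
        seq = core + dup + random_seq(rng, 1_000) + dup + random_seq(rng, 500)
        index = GenomeIndex(Genome("d", len(seq), sequence=seq))
        assert map_portion(dup[50:90], index).status == "multi"
        # brute-force occurrence count agrees
        assert len(index.occurrences(dup[50:90])) == 2

    def test_absent_sequence_is_unmapped(self, index):
        rng = np.random.default_rng(99)
        # 30-mer random sequences are absent from a 20 kb genome w.h.p.
        assert map_portion(random_seq(rng, 30), index).status == "unmapped"

    def test_query_shorter_than_seed_rejected(self, index):
        with pytest.raises(ValueError):
            map_portion("ACGTACGT", index)


class TestFilterTriple:
    def mk(self, r3pos, r3strand, r5pos, r5strand, status="unique"):
        return MappedTriple(
            dna=MapResult("unique", 0, "+", 24),
            rna3=MapResult(status, r3pos, r3strand, 20),
            rna5=MapResult("unique", r5pos, r5strand, 20),
        )

    def test_close_opposite_strand_pair_accepted(self):
        ok, reason = filter_triple(self.mk(1_000, "+", 1_100, "-"), 1_000_000)
        assert (ok, reason) == (True, "ok")

    def test_far_apart_rejected_with_reason(self):
        ok, reason = filter_triple(self.mk(1_000, "+", 13_020, "-"), 1_000_000)
        assert (ok, reason) == (False, "far_apart")

    def test_far_apart_uses_circular_distance(self):
        # linear separation huge, circular separation small -> accept
        ok, reason = filter_triple(self.mk(50, "+", 999_950, "-"), 1_000_000)
        assert ok

    def test_same_strand_rejected(self):
        ok, reason = filter_triple(self.mk(1_000, "+", 1_100, "+"), 1_000_000)
        assert (ok, reason) == (False, "same_strand")

    def test_non_unique_portion_rejected(self):
        ok, reason = filter_triple(self.mk(1_000, "+", 1_100, "-", status="multi"), 1_000_000)
        assert (ok, reason) == (False, "not_unique")


class TestProcessRun:
    def test_noiseless_run_recovers_every_contact_exactly(self, tmp_path, tiny_cfg, tiny_sim):
        genome, _, _, _, truth = tiny_sim
        emit_reads(truth, genome, tiny_cfg,
                   tmp_path / "r1.fq", tmp_path / "r2.fq", tmp_path / "s.tsv")
        contacts, stats = process_run(
            tmp_path / "r1.fq", tmp_path / "r2.fq", genome,
            tiny_cfg.bridge_sequence, switch_oligo=tiny_cfg.switch_oligo,
        )
        side = pd.read_csv(tmp_path / "s.tsv", sep="\t")
        merged = contacts.merge(side, on="read_id", suffixes=("", "_truth"))
        assert len(merged) == len(truth)
        assert (merged["rna3_pos"] == merged["rna3_pos_truth"]).all()
        assert (merged["dna_pos"] == merged["dna_pos_truth"]).all()
        assert (merged["rna3_strand"] == merged["rna_strand"]).all()
        s = stats.as_series()
        assert (s.diff().dropna() <= 0).all()  # monotone non-increasing cascade

    def test_recovered_rna_strand_is_opposite_of_source_gene(self, tmp_path, tiny_cfg, tiny_sim):
        genome, genes, _, _, truth = tiny_sim
        emit_reads(truth.head(400), genome, tiny_cfg,
                   tmp_path / "r1.fq", tmp_path / "r2.fq", tmp_path / "s.tsv")
        contacts, _ = process_run(
            tmp_path / "r1.fq", tmp_path / "r2.fq", genome,
            tiny_cfg.bridge_sequence, switch_oligo=tiny_cfg.switch_oligo,
        )
        side = pd.read_csv(tmp_path / "s.tsv", sep="\t")
        strand_of = {g.id: g.strand for g in genes}
        merged = contacts.merge(side, on="read_id")
        assert (
            merged["rna3_strand"]
            != merged["source_gene_id"].map(strand_of)
        ).all()

    def test_artifact_pairs_rejected_with_correct_reasons(self, tmp_path, tiny_cfg, tiny_sim):
        import dataclasses

        genome, _, _, _, truth = tiny_sim
        cfg = dataclasses.replace(tiny_cfg, artifact_fraction=0.4)
        emit_reads(truth.head(1_000), genome, cfg,
                   tmp_path / "r1.fq", tmp_path / "r2.fq", tmp_path / "s.tsv")
        contacts, stats = process_run(
            tmp_path / "r1.fq", tmp_path / "r2.fq", genome,
            cfg.bridge_sequence, switch_oligo=cfg.switch_oligo,
        )
        side = pd.read_csv(tmp_path / "s.tsv", sep="\t")
        bad = side[side["artifact"] != "none"]
        assert len(bad) > 100
        assert not set(bad["read_id"]) & set(contacts["read_id"])
        n_far = (side["artifact"] == "far").sum()
        n_same = (side["artifact"] == "same_strand").sum()
        assert stats.rejections.get("far_apart", 0) == n_far
        assert stats.rejections.get("same_strand", 0) == n_same

    def test_empty_fastq_yields_empty_table_and_zero_stats(self, tmp_path, tiny_sim):
        genome = tiny_sim[0]
        (tmp_path / "e1.fq").write_text("")
        (tmp_path / "e2.fq").write_text("")
        contacts, stats = process_run(
            tmp_path / "e1.fq", tmp_path / "e2.fq", genome, BRIDGE
        )
        assert len(contacts) == 0
        assert stats.total == 0 and stats.accepted == 0

    def test_catg_reattachment_preserves_dna_start_position(self, tiny_sim):
        genome, _, _, _, truth = tiny_sim
        index = GenomeIndex(genome)
        row = truth[truth["dna_strand"] == "+"].iloc[0]
        frag = genome.fetch(row.dna_pos - 21, row.dna_pos + 1)  # 22 nt incl. CATG
        core = frag[:-4]
        assert index.map_portion(reattach_catg(core)).pos == index.map_portion(frag).pos
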