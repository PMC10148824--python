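import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from redcmicro.core_genome import Gene
from redcmicro.profiles import (
    ConfigurationError,
    distance_bin_edges,
    interval_preference,
    interval_preference_table,
    operon_cumulative_map,
    updown_assign,
    updown_frequency_profile,
)
from conftest import make_contacts


# --------------------------------------------------------------------------
# Oracles


def walk_side(rna, dna, strand, L):
    """Literal circle walk in the transcription direction (slow, tiny L only)."""
    step = 1 if strand == "+" else -1
    down, x = 0, rna
    while x != dna:
        x = (x + step) % L
        down += 1
    up = (L - down) % L
    if down == 0:
        return "downstream", 0
    if down != up:
        return ("downstream", down) if down < up else ("upstream", up)
    # antipode: the far branch of the case table decides by the sign of rna - dna
    diff = rna - dna
    if strand == "+":
        return ("upstream" if diff < 0 else "downstream"), down
    return ("upstream" if diff > 0 else "downstream"), down


def arc_side_vectorized(rna, dna, strand, L):
    """Arithmetic form of the walking oracle (validated against walk_side)."""
    down = (dna - rna) % L if strand == "+" else (rna - dna) % L
    up = (L - down) % L
    dist = np.minimum(down, up)
    side = np.where(down < up, "downstream", "upstream")
    tie_far = down == up
    diff = rna - dna
    if strand == "+":
        far_side = np.where(diff < 0, "upstream", "downstream")
    else:
        far_side = np.where(diff > 0, "upstream", "downstream")
    side = np.where(tie_far, far_side, side)
    side = np.where(down == 0, "downstream", side)
    return side, dist


class TestUpdownAssign:
    def test_sense_nearby_downstream(self):
        side, dist, tie = updown_assign(100_000, 100_050, "+", 1_000_000)
        assert (side, dist, tie) == ("downstream", 50, False)

    def test_antisense_nearby_downstream(self):
        side, dist, tie = updown_assign(100_000, 99_950, "-", 1_000_000)
        assert (side, dist, tie) == ("downstream", 50, False)

    def test_sense_wraparound_upstream(self):
        side, dist, tie = updown_assign(10, 980, "+", 1_000)
        assert (side, dist, tie) == ("upstream", 30, False)

    def test_tie_at_zero_distance_flagged(self):
        side, dist, tie = updown_assign(5, 5, "+", 1_000)
        assert (dist, tie) == (0, True)
        assert side == "downstream"

    @pytest.mark.parametrize("L", [3, 8, 17, 32])
    def test_matches_literal_walk_exhaustively_on_tiny_circles(self, L):
        for strand in "+-":
            for rna in range(L):
                for dna in range(L):
                    side, dist, _ = updown_assign(rna, dna, strand, L)
                    assert (side, dist) == walk_side(rna, dna, strand, L)

    @pytest.mark.parametrize("L", [31, 64])
    def test_arithmetic_oracle_agrees_with_literal_walk(self, L):
        for strand in "+-":
            rna, dna = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
            side, dist = arc_side_vectorized(rna.ravel(), dna.ravel(), strand, L)
            for r, d, s, di in zip(rna.ravel(), dna.ravel(), side, dist):
                assert (s, di) == walk_side(int(r), int(d), strand, L)


# --------------------------------------------------------------------------
# Interval preference


GENE = Gene("g", 1_199_000, 1_201_000, "+")  # middle at 1.2 Mb
L_BIG = 2_400_000


def contacts_for_gene(dna_pos):
    return make_contacts(
        np.full(len(dna_pos), 1_200_000), np.asarray(dna_pos),
        gene_id="g", rna_class="mRNA",
    )


class TestIntervalPreference:
    def test_all_contacts_in_parental_interval(self):
        c = contacts_for_gene(np.full(600, 1_200_500))
        p = interval_preference(c, GENE, L_BIG)
        assert p.counts.tolist() == [600, 0, 0, 0]
        assert p.rel_freq[0] == pytest.approx(L_BIG / 10_000)  # = 240
        assert p.rel_freq[1:].tolist() == [0, 0, 0]

    def test_uniform_contacts_are_flat(self):
        rng = np.random.default_rng(17)
        c = contacts_for_gene(rng.integers(0, L_BIG, 100_000))
        p = interval_preference(c, GENE, L_BIG)
        assert np.all(np.abs(p.rel_freq - 1) < 0.1)

    def test_conservation_and_normalization_identity(self):
        rng = np.random.default_rng(23)
        c = contacts_for_gene(rng.integers(0, L_BIG, 3_000))
        p = interval_preference(c, GENE, L_BIG)
        assert p.counts.sum() + p.masked_count == 3_000
        weighted = (p.rel_freq * p.lengths).sum() / p.lengths.sum()
        assert weighted == pytest.approx(1.0)

    def test_mask_removes_counts_and_lengths_consistently(self):
        rng = np.random.default_rng(29)
        c = contacts_for_gene(rng.integers(0, L_BIG, 100_000))
        mask = [(GENE.start, GENE.end)]  # flank-only variant: hide the parental locus
        p = interval_preference(c, GENE, L_BIG, mask=mask)
        full = interval_preference(c, GENE, L_BIG)
        assert p.counts.sum() + p.masked_count == full.counts.sum()
        assert p.lengths[0] == pytest.approx(10_000 - GENE.span(L_BIG), abs=1)
        # uniform input stays flat after masking
        assert np.all(np.abs(p.rel_freq - 1) < 0.1)
        weighted = (p.rel_freq * p.lengths).sum() / p.lengths.sum()
        assert weighted == pytest.approx(1.0)

    def test_short_genome_with_canonical_edges_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            interval_preference(contacts_for_gene([0]), GENE, 900_000)

    def test_low_count_rna_flagged_not_errored(self):
        p = interval_preference(contacts_for_gene([1_200_100] * 20), GENE, L_BIG)
        assert not p.passed_filter

    def test_table_applies_contact_filter(self, study_cfg, study_sim):
        from redcmicro.contacts import assign_rna_to_genes

        _, genes, _, _, truth = study_sim
        assigned = assign_rna_to_genes(truth, genes, study_cfg.L)
        tab = interval_preference_table(assigned, genes, study_cfg.L)
        assert (tab["total"] >= 500).all()
        counts = assigned["gene_id"].value_counts()
        assert set(tab["rna_id"]) == set(counts[counts >= 500].index)

    def test_drag_model_mrna_prefers_parental_interval(self, study_cfg, study_sim):
        from redcmicro.contacts import assign_rna_to_genes

        _, genes, _, _, truth = study_sim
        assigned = assign_rna_to_genes(truth, genes, study_cfg.L)
        # robustness threshold scaled to simulated depth (1e5 vs tens of
        # millions of contacts in a real library)
        tab = interval_preference_table(assigned, genes, study_cfg.L, min_contacts=100)
        mrna = tab[tab["rna_class"] == "mRNA"]
        assert len(mrna) > 50
        assert (mrna["relfreq_I1"] > 1).all()
        assert (mrna["relfreq_I1"] > mrna["relfreq_I4"]).all()


@given(seed=st.integers(0, 10_000), n=st.integers(1, 300))
def test_interval_counts_always_conserve_contacts(seed, n):
    rng = np.random.default_rng(seed)
    c = contacts_for_gene(rng.integers(0, L_BIG, n))
    mask = [(1_100_000, 1_260_000)]
    p = interval_preference(c, GENE, L_BIG, mask=mask)
    assert p.counts.sum() + p.masked_count == n


# --------------------------------------------------------------------------
# Up/down frequency profile


def uniform_updown_contacts(rng, L, n, gene):
    return make_contacts(
        rng.integers(gene.start, gene.end, n), rng.integers(0, L, n),
        gene_id=gene.id, rna_class="mRNA",
    )


class TestUpdownProfile:
    def test_bins_partition_all_distances(self):
        L = 10_000
        edges = distance_bin_edges(L)
        assert edges[0] == 0 and edges[-1] == L // 2 + 1
        d = np.arange(0, L // 2 + 1)
        idx = np.searchsorted(edges, d, side="right") - 1
        assert idx.min() >= 0 and idx.max() == len(edges) - 2
        counts = np.bincount(idx, minlength=len(edges) - 1)
        assert counts.sum() == len(d)

    def test_single_downstream_contact_binning_arithmetic(self):
        L = 100_000
        gene = Gene("g", 40_000, 42_000, "+")
        c = make_contacts([41_000], [41_070], gene_id="g", rna_class="mRNA")
        prof = updown_frequency_profile(c, [gene], L)
        row = prof[(prof["bin_lo"] == 64)].iloc[0]
        assert row["down_count"] == 1
        assert row["down_freq"] == pytest.approx(1 / 64)
        assert prof["up_count"].sum() == 0

    def test_uniform_input_profiles_statistically_indistinguishable(self):
        rng = np.random.default_rng(31)
        L = 4_096
        gene = Gene("g", 1_000, 3_000, "+")
        prof = updown_frequency_profile(
            uniform_updown_contacts(rng, L, 100_000, gene), [gene], L
        )
        m = (prof["up_count"] + prof["down_count"]) > 0
        alpha = 0.01 / m.sum()  # Bonferroni over populated bins
        for _, row in prof[m].iterrows():
            n = int(row["up_count"] + row["down_count"])
            p = stats.binomtest(int(row["down_count"]), n, 0.5).pvalue
            assert p > alpha

    def test_empty_input_yields_empty_profile(self):
        c = make_contacts([], [], gene_id=[], rna_class=[])
        prof = updown_frequency_profile(c, [], 10_000)
        assert len(prof) == 0

    def test_drag_ratio_above_one_at_short_range_flat_beyond(self, study_cfg, study_sim):
        from redcmicro.contacts import assign_rna_to_genes

        _, genes, operons, _, truth = study_sim
        assigned = assign_rna_to_genes(truth, genes, study_cfg.L)
        prof = updown_frequency_profile(assigned, genes, study_cfg.L)
        spans = np.array([o.span(study_cfg.L) for o in operons])
        median_span, max_span = np.median(spans), spans.max()
        short = prof[prof["bin_hi"] <= median_span]
        far = prof[prof["bin_lo"] >= max_span]
        assert len(short) >= 3 and len(far) >= 2
        assert (short["ratio"] > 1).all()
        assert np.all(np.abs(far["ratio"] - 1) < 0.15)


# --------------------------------------------------------------------------
# Cumulative operon maps


class TestOperonMap:
    def test_window_and_bin_arithmetic(self):
        from redcmicro.core_genome import Operon

        L = 100_000
        op = Operon("op", ("g",), 50_000, 51_200, "+")
        # window = operon +/- half-operon flanks = 2400 bp -> bin width 100 bp
        c = make_contacts([49_400, 50_000], [49_401, 51_750],
                          gene_id="g", rna_class="mRNA")
        maps = operon_cumulative_map(c, [op], L)
        m = maps["sense"]
        assert m.n_operons == 1
        assert m.counts[0, 0] == 1  # both coords in the first 100 bp of the window
        assert m.counts[6, 23] == 1  # operon start bin x last flank bin
        assert m.counts.sum() == 2

    def test_contacts_outside_window_ignored(self):
        from redcmicro.core_genome import Operon

        op = Operon("op", ("g",), 50_000, 51_200, "+")
        c = make_contacts([10_000], [10_000], gene_id="g", rna_class="mRNA")
        maps = operon_cumulative_map(c, [op], 100_000)
        assert maps["sense"].counts.sum() == 0

    def test_sense_mass_above_antisense_mass_below_diagonal(self, study_cfg, study_sim):
        from redcmicro.contacts import assign_rna_to_genes

        _, genes, operons, _, truth = study_sim
        assigned = assign_rna_to_genes(truth, genes, study_cfg.L)
        maps = operon_cumulative_map(assigned, operons, study_cfg.L)
        s, a = maps["sense"], maps["antisense"]
        assert s.n_operons + a.n_operons == len(operons)
        assert s.mass_above_diagonal() / (s.mass_above_diagonal() + s.mass_below_diagonal()) > 0.55
        assert a.mass_below_diagonal() / (a.mass_above_diagonal() + a.mass_below_diagonal()) > 0.55
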