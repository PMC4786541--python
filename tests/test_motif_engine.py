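"""Observed counts, per-gene/per-set profiles, strand handling, k-mer sweep."""

import math

import numpy as np
import pytest

from conftest import make_cds, naive_matches
from distamo import (
    build_codon_ngram_table,
    gene_profile,
    genome_scan,
    kmer_sweep,
    merge_profiles,
    observed_count,
    synthetic,
)
from distamo.codon_model import codon_span, enumerate_potential_windows, reverse_complement
from distamo.genome_io import assign_replication_context
from distamo.motif_engine import MotifProfile
from distamo.stats import zscore


class TestObservedCount:
    def test_arg_ser_gene_counts_one(self, pool_table):
        cds = make_cds("ATGAGATCCAAA")
        assert observed_count(cds, "GATC", pool_table) == 1

    def test_palindrome_counts_equal_on_template(self, pool_table):
        cds = make_cds("ATGAGATCCAAA")
        assert observed_count(cds, "GATC", pool_table, strand_mode="template") == 1

    def test_tandem_overlap_matches_naive_scan(self, pool_table):
        # AGATCGATCC hosts tandem GATC occurrences
        cds = make_cds("ATGAGATCGATCCAA")  # M R S I Q
        wins = enumerate_potential_windows(cds, "GATC", pool_table)
        keys = {w.nt_offset for w in wins}
        naive = sum(
            1
            for q in range(len(cds.nucleotides) - 3)
            if naive_matches(cds.nucleotides, q, "GATC")
            and (q // 3) + codon_span(4, q % 3) <= cds.n_codons
            and q in keys
        )
        assert observed_count(cds, "GATC", pool_table) == naive == 2


class TestGeneProfile:
    def test_all_certain_windows_give_z_zero(self):
        # poly-Trp: every TGG window is forced (P = 1) and realized
        cds = make_cds("ATG" + "TGG" * 10)
        table = build_codon_ngram_table([cds], 2)
        prof = gene_profile(cds, "TGG", table)
        assert prof.s == 0 and prof.m == prof.m_bar
        assert prof.z == 0.0

    def test_windowless_gene_z_is_missing_not_zero(self, pool_table):
        cds = make_cds("ATG" + "AAA" * 10)
        prof = gene_profile(cds, "GATC", pool_table)
        assert prof.n_windows == 0 and prof.z is None

    def test_hand_computed_moments(self, uniform_table):
        # M R S K R S: two RS windows, each P = 8/36 under the uniform table
        cds = make_cds("ATGAGATCCAAACGTTCA")  # M R S K R S
        prof = gene_profile(cds, "GATC", uniform_table)
        p = 8 / 36
        assert prof.probabilities == (p, p)
        assert prof.m_bar == pytest.approx(2 * p)
        assert prof.s == pytest.approx(math.sqrt(2 * p * (1 - p)))
        assert prof.m == 1  # only the first RS is realized (AGA TCC)
        assert prof.z == pytest.approx((1 - 2 * p) / math.sqrt(2 * p * (1 - p)))

    def test_planted_enrichment_direction(self, pool_table):
        hot = synthetic.random_coding_sequence(
            synthetic.SyntheticSpec(3000, "GATC", 20, 20, seed=5)
        )
        cold = synthetic.random_coding_sequence(
            synthetic.SyntheticSpec(3000, "GATC", 40, 0, seed=6)
        )
        assert gene_profile(hot, "GATC", pool_table).z > 2
        assert gene_profile(cold, "GATC", pool_table).z < -2


class TestMergeProfiles:
    def test_merge_single_is_identity(self, pool_table, control_pool):
        prof = gene_profile(control_pool[0], "GATC", pool_table)
        merged = merge_profiles([prof])
        assert merged.z == prof.z and merged.m == prof.m

    def test_moment_additivity(self, pool_table, control_pool):
        a = gene_profile(control_pool[0], "GATC", pool_table)
        b = gene_profile(control_pool[1], "GATC", pool_table)
        merged = merge_profiles([a, b])
        assert merged.m_bar == pytest.approx(a.m_bar + b.m_bar)
        assert merged.s**2 == pytest.approx(a.s**2 + b.s**2)

    def test_merged_z_equals_recomputation_from_scratch(self, pool_table, control_pool):
        genes = control_pool[:10]
        merged = merge_profiles([gene_profile(g, "GATC", pool_table) for g in genes])
        probs, m = [], 0
        for g in genes:
            wins = enumerate_potential_windows(g, "GATC", pool_table)
            probs += [w.probability for w in wins]
            m += observed_count(g, "GATC", pool_table)
        m_bar = sum(probs)
        s = math.sqrt(sum(p * (1 - p) for p in probs))
        assert merged.z == pytest.approx(zscore(m, m_bar, s), rel=1e-12)

    def test_mixed_motifs_rejected(self, pool_table, control_pool):
        a = gene_profile(control_pool[0], "GATC", pool_table)
        b = gene_profile(control_pool[1], "AGAT", pool_table)
        with pytest.raises(ValueError):
            merge_profiles([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_profiles([])


class TestStrandSymmetry:
    def test_palindromic_motif_coding_equals_template(self, bias_genome):
        table = build_codon_ngram_table(bias_genome.cds_list, 2)
        tab = genome_scan(bias_genome.cds_list, "GATC", table)
        finite = tab.dropna(subset=["z_coding", "z_template"])
        assert len(finite) > 0
        assert np.allclose(finite["z_coding"], finite["z_template"])

    def test_reverse_complement_duality(self, pool_table, control_pool):
        motif = "GGCAAT"
        for cds in control_pool[:5]:
            zt = gene_profile(cds, motif, pool_table, strand_mode="template").z
            zc = gene_profile(cds, reverse_complement(motif), pool_table).z
            if zt is None:
                assert zc is None
            else:
                assert zt == pytest.approx(zc, rel=1e-12)

    def test_leading_mode_picks_strand_by_context(self, bias_genome):
        table = build_codon_ngram_table(bias_genome.cds_list, 3)
        ctx = assign_replication_context(bias_genome.replicon, bias_genome.cds_list)
        by_id = {c.gene_id: c for c in ctx}
        motif = "GGCAAT"
        for cds in bias_genome.cds_list[:6]:
            c = by_id[cds.gene_id]
            z_lead = gene_profile(cds, motif, table, "leading", c).z
            expected_mode = "coding" if c.strand_class == "leading" else "template"
            assert z_lead == gene_profile(cds, motif, table, expected_mode).z


class TestKmerSweep:
    def test_k1_gives_four_rows(self, pool_table, control_pool):
        sweep = kmer_sweep(control_pool[:5], 1, pool_table)
        assert list(sweep.index) == ["A", "C", "G", "T"]

    def test_planted_motif_ranks_first_of_256(self, pool_table):
        genes = [
            synthetic.random_coding_sequence(
                synthetic.SyntheticSpec(1500, "GATC", 20, 20, seed=100 + i),
                gene_id=f"e{i}",
            )
            for i in range(8)
        ]
        sweep = kmer_sweep(genes, 4, pool_table)
        assert sweep["z"].idxmax() == "GATC"

    def test_set_sweep_agrees_with_single_motif_route(self, pool_table, control_pool):
        genes = control_pool[:12]
        sweep = kmer_sweep(genes, 4, pool_table)
        for motif in ["GATC", "TTTT", "CGCG", "AGAT"]:
            merged = merge_profiles([gene_profile(g, motif, pool_table) for g in genes])
            row = sweep.loc[motif]
            assert row["n_windows"] == merged.n_windows
            assert row["m"] == merged.m
            assert row["m_bar"] == pytest.approx(merged.m_bar, rel=1e-9)
            assert row["z"] == pytest.approx(merged.z, rel=1e-9)

    def test_self_table_set_scores_are_null(self, control_pool):
        """With frequencies from the scored set itself, the set-level
        expectation telescopes to the observed count for every k-mer."""
        genes = control_pool[:20]
        table = build_codon_ngram_table(genes, 2)
        sweep = kmer_sweep(genes, 4, table)
        present = sweep[sweep["n_windows"] > 0]
        assert np.allclose(present["m"], present["m_bar"], atol=1e-8)

    def test_null_significance_rate_is_nominal(self, pool_table, control_pool):
        """Per-gene tetramer z-scores on random genes are significant at
        roughly the normal-tail rate (well below 15%)."""
        per_gene = kmer_sweep(control_pool[:30], 4, pool_table, per_gene=True)
        finite = per_gene[np.isfinite(per_gene["z"]) & (per_gene["n_windows"] >= 5)]
        rate = (finite["z"].abs() >= 2).mean()
        assert 0.001 < rate < 0.15


def test_profile_invariant_checks():
    with pytest.raises(ValueError, match="observed count"):
        MotifProfile("g", "GATC", "coding", (0.5,), 2)
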