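"""Codon-span rule, n-gram table, P_mot and potential-window enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_cds, naive_pmot, naive_window_scan
from distamo import build_codon_ngram_table, synthetic
from distamo.codon_model import (
    CodonNgramTable,
    MotifError,
    ProteomeIndex,
    codon_span,
    enumerate_potential_windows,
    expand_iupac,
    motif_probability,
    parse_motif,
    reverse_complement,
)


class TestCodonSpan:
    @pytest.mark.parametrize(
        "l,p,expected",
        [(4, 0, 2), (4, 1, 2), (4, 2, 2),  # GATC-sized: always two codons
         (3, 0, 1), (3, 1, 2), (3, 2, 2),
         (8, 0, 3), (8, 1, 3), (8, 2, 4)],  # KOPS-sized
    )
    def test_values(self, l, p, expected):
        assert codon_span(l, p) == expected

    @pytest.mark.parametrize("l", range(1, 13))
    def test_span_set_follows_length_rule(self, l):
        spans = {codon_span(l, p) for p in (0, 1, 2)}
        if l % 3 == 0:
            assert spans == {l // 3, l // 3 + 1}
        elif l % 3 == 1:
            assert spans == {l // 3 + 1}
        else:
            assert spans == {l // 3 + 1, l // 3 + 2}

    def test_rejects_bad_offset(self):
        with pytest.raises(MotifError):
            codon_span(4, 3)


class TestNgramTable:
    def test_single_cds_counts(self):
        cds = make_cds("ATGGAT")  # stop already absent
        t = build_codon_ngram_table([cds], 2)
        assert dict(t.counts[1]) == {"ATG": 1, "GAT": 1}
        assert dict(t.counts[2]) == {"ATGGAT": 1}

    def test_stop_is_trimmed_before_counting(self):
        from distamo.genome_io import make_coding_sequence

        cds = make_coding_sequence("g", 0, 9, "+", "ATGGATTAA")
        t = build_codon_ngram_table([cds], 2)
        assert dict(t.counts[1]) == {"ATG": 1, "GAT": 1}

    def test_two_identical_cds_double_counts(self):
        cds = make_cds("ATGGATAAA")
        t1 = build_codon_ngram_table([cds], 2)
        t2 = build_codon_ngram_table([cds, cds], 2)
        for k in (1, 2):
            assert {c: 2 * n for c, n in t1.counts[k].items()} == dict(t2.counts[k])

    def test_totals_match_window_arithmetic(self):
        rng = np.random.default_rng(3)
        lengths = [int(rng.integers(20, 80)) for _ in range(20)]
        genes = [make_cds(synthetic.random_gene(n, rng)) for n in lengths]
        t = build_codon_ngram_table(genes, 3)
        for k in (1, 2, 3):
            assert t.total(k) == sum(n - k + 1 for n in lengths)

    def test_empty_cds_list_rejected(self):
        with pytest.raises(ValueError):
            build_codon_ngram_table([], 2)


class TestMotifProbability:
    def test_trp_forces_tgg(self, uniform_table):
        assert motif_probability("W", 0, "TGG", uniform_table) == 1.0

    def test_arg_ser_gatc_worked_example(self, uniform_table):
        # Arg codons ending GA (CGA, AGA) x Ser codons starting TC
        # (TCT, TCC, TCA, TCG) = 8 of the 6x6 codon pairs
        assert motif_probability("RS", 1, "GATC", uniform_table) == pytest.approx(
            8 / 36, abs=1e-15
        )

    @pytest.mark.parametrize("p", [0, 1, 2])
    def test_lys_lys_never_hosts_gatc(self, uniform_table, p):
        span = codon_span(4, p)
        assert motif_probability("K" * span, p, "GATC", uniform_table) == 0.0

    def test_unobserved_window_is_none(self):
        t = CodonNgramTable(2)
        t.counts[1]["ATG"] = 1
        assert motif_probability("RS", 1, "GATC", t) is None

    def test_scaling_invariance(self, pool_table):
        scaled = CodonNgramTable(pool_table.max_span)
        for k in scaled.counts:
            for c, n in pool_table.counts[k].items():
                scaled.counts[k][c] = 7 * n
        for pep, p, motif in [("RS", 1, "GATC"), ("DG", 0, "GATC"), ("LI", 2, "GATC")]:
            assert motif_probability(pep, p, motif, pool_table) == pytest.approx(
                motif_probability(pep, p, motif, scaled), rel=1e-12
            )

    def test_degenerate_motif_dominates_expansions(self, pool_table):
        for pep, p in [("RS", 1), ("DG", 0), ("GS", 1)]:
            degen = motif_probability(pep, p, "GRTC", pool_table)
            for concrete in expand_iupac("GRTC"):
                single = motif_probability(pep, p, concrete, pool_table)
                assert degen >= single

    def test_window_length_mismatch_rejected(self, uniform_table):
        with pytest.raises(MotifError, match="spans"):
            motif_probability("RSK", 1, "GATC", uniform_table)

    def test_matches_bruteforce_oracle(self, pool_table, control_pool):
        """Randomized cross-check against the naive enumeration oracle."""
        rng = np.random.default_rng(11)
        peps = [c.peptide for c in control_pool]
        for _ in range(150):
            motif = "".join("ACGT"[i] for i in rng.integers(4, size=4))
            p = int(rng.integers(3))
            span = codon_span(4, p)
            src = peps[rng.integers(len(peps))]
            j = int(rng.integers(len(src) - span))
            pep = src[j : j + span]
            assert motif_probability(pep, p, motif, pool_table) == naive_pmot(
                pep, p, motif, pool_table
            )


class TestWindowEnumeration:
    def test_arg_ser_gene_has_one_gatc_window(self, pool_table):
        cds = make_cds("ATGAGATCCAAA")  # MRSK via ATG AGA TCC AAA
        wins = enumerate_potential_windows(cds, "GATC", pool_table)
        assert len(wins) == 1
        (w,) = wins
        assert (w.nt_offset, w.codon_offset, w.peptide_window) == (4, 1, "RS")
        assert w.span == 2 and 0 < w.probability <= 1

    def test_poly_lys_gene_has_none(self, pool_table):
        cds = make_cds("ATG" + "AAA" * 20)
        assert enumerate_potential_windows(cds, "GATC", pool_table) == []

    def test_single_base_motif_matches_naive_scan(self, pool_table):
        rng = np.random.default_rng(5)
        cds = make_cds(synthetic.random_gene(40, rng))
        wins = enumerate_potential_windows(cds, "G", pool_table)
        assert {(w.nt_offset, w.codon_offset) for w in wins} == naive_window_scan(
            cds, "G", pool_table
        )

    @pytest.mark.parametrize("motif", ["GATC", "GGGNAGGG", "AGAT"])
    def test_indexed_scan_equals_naive_scan(self, motif, control_pool, pool_table):
        """The proteome-index search returns the identical window set as a
        per-position brute-force scan (50-gene fixture)."""
        genes = control_pool[:50]
        index = ProteomeIndex.for_motif_length(genes, len(parse_motif(motif)))
        hits = index.scan(motif, pool_table)
        for cds in genes:
            per_gene = enumerate_potential_windows(cds, motif, pool_table)
            assert hits[cds.gene_id] == per_gene
            assert {(w.nt_offset, w.codon_offset) for w in per_gene} == \
                naive_window_scan(cds, motif, pool_table)

    def test_realized_motifs_always_covered(self, bias_genome):
        """Every realized motif occurrence lies in a potential window with
        P > 0 when scored against the genome's own table."""
        from distamo.codon_model import matches_at

        table = build_codon_ngram_table(bias_genome.cds_list, 3)
        motif = "GGCAAT"
        for cds in bias_genome.cds_list[:10]:
            wins = enumerate_potential_windows(cds, motif, table)
            keys = {(w.nt_offset, w.codon_offset) for w in wins}
            nt = cds.nucleotides
            for q in range(len(nt) - len(motif) + 1):
                if matches_at(nt, q, motif):
                    j, p = q // 3, q % 3
                    if j + codon_span(len(motif), p) <= cds.n_codons:
                        assert (q, p) in keys


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=8))
def test_reverse_complement_involution(motif):
    assert reverse_complement(reverse_complement(motif)) == parse_motif(motif)
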