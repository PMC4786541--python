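"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (exhaustive
enumeration, per-position brute force) kept separate from the library's
indexed/cached code paths.
"""

import itertools

import numpy as np
import pytest
from Bio.Data import CodonTable

from distamo import build_codon_ngram_table, synthetic
from distamo.codon_model import CodonNgramTable, codon_span, matches_at
from distamo.genome_io import CodingSequence

TAB11 = CodonTable.unambiguous_dna_by_id[11]
SENSE_CODONS = sorted(TAB11.forward_table)
BACK = {}
for codon, aa in TAB11.forward_table.items():
    BACK.setdefault(aa, []).append(codon)
for aa in BACK:
    BACK[aa] = sorted(BACK[aa])

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def naive_matches(seq: str, pos: int, motif: str) -> bool:
    if pos < 0 or pos + len(motif) > len(seq):
        return False
    return all(seq[pos + i] in IUPAC[b] for i, b in enumerate(motif))


def naive_pmot(pep: str, p: int, motif: str, table: CodonNgramTable):
    """Brute-force P_mot: enumerate every synonymous codon string of the
    window, weight by table counts, split by motif match at offset p."""
    num = den = 0
    for combo in itertools.product(*[BACK[aa] for aa in pep]):
        cod = "".join(combo)
        w = table.counts[len(pep)].get(cod, 0)
        den += w
        if naive_matches(cod, p, motif):
            num += w
    return None if den == 0 else num / den


def naive_window_scan(cds: CodingSequence, motif: str, table: CodonNgramTable):
    """Per-position brute-force potential-window scan of one gene.

    Returns the set of (nt_offset, codon_offset) keys with P_mot > 0.
    """
    out = set()
    pep = cds.peptide
    for p in (0, 1, 2):
        span = codon_span(len(motif), p)
        for j in range(cds.n_codons - span + 1):
            prob = naive_pmot(pep[j : j + span], p, motif, table)
            if prob:
                out.add((3 * j + p, p))
    return out


def pb_enumeration(probs):
    """Exhaustive-outcome mean and sd of a Poisson-binomial count."""
    p = np.asarray(probs, dtype=float)
    n = p.size
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    weights = np.prod(np.where(masks == 1, p, 1 - p), axis=1)
    counts = masks.sum(axis=1)
    mean = float((weights * counts).sum())
    var = float((weights * counts**2).sum()) - mean**2
    return mean, float(np.sqrt(max(var, 0.0)))


def make_cds(nt: str, gene_id: str = "g") -> CodingSequence:
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    return CodingSequence(
        gene_id=gene_id, start=0, end=len(nt), strand="+", nucleotides=nt,
        peptide=synthetic._translate(codons), midpoint=len(nt) // 2,
    )


@pytest.fixture(scope="session")
def uniform_table():
    """Codon table with every 1- and 2-gram given unit count (the 'uniform
    codon-pair' null of the worked examples)."""
    t = CodonNgramTable(2)
    for c in SENSE_CODONS:
        t.counts[1][c] = 1
    for a, b in itertools.product(SENSE_CODONS, repeat=2):
        t.counts[2][a + b] = 1
    return t


@pytest.fixture(scope="session")
def control_pool():
    """150 plain random coding sequences (uniform codon background)."""
    rng = np.random.default_rng(2024)
    return [
        make_cds(synthetic.random_gene(300, rng), f"ctrl{i:03d}")
        for i in range(150)
    ]


@pytest.fixture(scope="session")
def pool_table(control_pool):
    return build_codon_ngram_table(control_pool, 4)


@pytest.fixture(scope="session")
def bias_genome():
    """Circular fixture genome with a non-palindromic motif planted into
    leading-strand genes only."""
    return synthetic.leading_bias_genome(seed=505)


@pytest.fixture(scope="session")
def six_gene_genome():
    """Small mixed-strand genome (3 plus, 3 minus) for I/O tests."""
    rng = np.random.default_rng(7)
    seqs = [synthetic.random_gene(60, rng) for _ in range(6)]
    ids = [f"gene{i}" for i in range(6)]
    return synthetic.assemble_genome(
        seqs, ids, strands=["+", "-", "+", "-", "+", "-"], ori_position=0, seed=77
    )
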