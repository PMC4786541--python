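"""The codon-redundancy null model.

A DNA motif of length ``l`` starting at offset ``p`` (0, 1 or 2) within a
codon spans ``ceil((p + l) / 3)`` consecutive codons. A *potential motif* is
a position in a coding region where the encoded amino-acid window admits the
motif through synonymous codon choice. Its realization probability is

    P_mot(pep) = sum of genome-wide frequencies of codon strings that encode
                 ``pep`` AND contain the motif at the given offset,
                 divided by the sum over all codon strings encoding ``pep``,

with codon k-gram frequencies counted in frame over all coding sequences of
the genome. No smoothing is applied: a peptide window whose codon strings
are entirely unobserved in the genome cannot be assigned a probability and
is excluded from the analysis (flagged as unobserved).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .genome_io import CodingSequence

_IUPAC = {k: frozenset(v) for k, v in ambiguous_dna_values.items()}


class MotifError(ValueError):
    pass


def parse_motif(motif: str) -> str:
    """Normalize an IUPAC nucleotide motif (case-insensitive)."""
    m = motif.strip().upper()
    if not m:
        raise MotifError("empty motif")
    bad = set(m) - set(_IUPAC)
    if bad:
        raise MotifError(f"invalid IUPAC letters in motif: {sorted(bad)}")
    return m


def reverse_complement(motif: str) -> str:
    return str(Seq(parse_motif(motif)).reverse_complement())


def matches_at(sequence: str, pos: int, motif: str) -> bool:
    """True when the concrete sequence matches the IUPAC motif at ``pos``."""
    if pos < 0 or pos + len(motif) > len(sequence):
        return False
    return all(sequence[pos + i] in _IUPAC[m] for i, m in enumerate(motif))


def codon_span(l: int, p: int) -> int:
    """Number of codons a motif of length ``l`` covers when it starts at
    in-codon offset ``p``."""
    if l < 1:
        raise MotifError("motif length must be >= 1")
    if p not in (0, 1, 2):
        raise MotifError("codon offset must be 0, 1 or 2")
    return -(-(p + l) // 3)  # ceil


def back_table(translation_table: int = 11) -> dict[str, tuple[str, ...]]:
    """Amino acid -> tuple of synonymous codons (sense codons only)."""
    tab = CodonTable.unambiguous_dna_by_id[translation_table]
    back: dict[str, list[str]] = defaultdict(list)
    for codon, aa in sorted(tab.forward_table.items()):
        back[aa].append(codon)
    return {aa: tuple(cods) for aa, cods in back.items()}


class CodonNgramTable:
    """Genome-wide in-frame codon k-gram counts, k = 1 .. max_span.

    Counts are accumulated over consecutive in-frame codons within single
    coding sequences (never across gene boundaries); the trailing stop codon
    is already trimmed by CDS validation.
    """

    def __init__(self, max_span: int, translation_table: int = 11):
        if max_span < 1:
            raise ValueError("max_span must be >= 1")
        self.max_span = max_span
        self.translation_table = translation_table
        self.counts: dict[int, Counter] = {k: Counter() for k in range(1, max_span + 1)}
        self._back = back_table(translation_table)
        self._pmot_cache: dict[tuple[str, int, str], float | None] = {}

    def add_cds(self, cds: CodingSequence) -> None:
        nt = cds.nucleotides
        n = len(nt) // 3
        for k in range(1, self.max_span + 1):
            w = 3 * k
            self.counts[k].update(nt[3 * i : 3 * i + w] for i in range(n - k + 1))
        self._pmot_cache.clear()

    def count(self, codon_string: str) -> int:
        k = len(codon_string) // 3
        if k < 1 or k > self.max_span or len(codon_string) % 3:
            raise ValueError(f"bad codon string length {len(codon_string)}")
        return self.counts[k].get(codon_string, 0)

    def total(self, k: int) -> int:
        return sum(self.counts[k].values())

    def codon_weights(self, aa: str) -> tuple[tuple[str, ...], list[int]]:
        """Synonymous codons of ``aa`` with their genome-wide 1-gram counts."""
        cods = self._back[aa]
        return cods, [self.counts[1].get(c, 0) for c in cods]

    def synonymous_codons(self, aa: str) -> tuple[str, ...]:
        return self._back[aa]


def build_codon_ngram_table(
    cds_list: list[CodingSequence], max_span: int, translation_table: int = 11
) -> CodonNgramTable:
    """Count every in-frame codon k-gram, k = 1..max_span, over all CDSs."""
    if not cds_list:
        raise ValueError("empty CDS list")
    table = CodonNgramTable(max_span, translation_table)
    for cds in cds_list:
        table.add_cds(cds)
    return table


def _codings(pep: str, back: dict[str, tuple[str, ...]]):
    try:
        pools = [back[aa] for aa in pep]
    except KeyError as exc:
        raise MotifError(f"unknown amino acid {exc} in window {pep!r}") from exc
    for combo in itertools.product(*pools):
        yield "".join(combo)


def motif_probability(
    peptide_window: str, p: int, motif: str, table: CodonNgramTable
) -> float | None:
    """P_mot for one peptide window and in-codon offset.

    Enumerates every codon string encoding the window; the numerator sums
    the genome-wide counts of those containing the (IUPAC) motif at offset
    ``p``, the denominator the counts of all of them. Returns ``None`` when
    the denominator is zero (window peptide never observed in the genome:
    the window is unusable and must be excluded from both the expectation
    and the observed count).
    """
    motif = parse_motif(motif)
    span = codon_span(len(motif), p)
    if len(peptide_window) != span:
        raise MotifError(
            f"window {peptide_window!r} has {len(peptide_window)} residues, "
            f"motif of length {len(motif)} at offset {p} spans {span} codons"
        )
    key = (peptide_window, p, motif)
    cache = table._pmot_cache
    if key in cache:
        return cache[key]
    num = den = 0
    for cod in _codings(peptide_window, table._back):
        w = table.count(cod)
        if w == 0:
            continue
        den += w
        if matches_at(cod, p, motif):
            num += w
    out = None if den == 0 else num / den
    cache[key] = out
    return out


@dataclass(frozen=True)
class PotentialMotif:
    """One potential-motif window: a peptide window and codon offset where
    synonymous codon choice permits the motif, with realization probability."""

    gene_id: str
    nt_offset: int  # 0-based position of the motif's first base in the CDS
    codon_offset: int  # position of that base within its codon (0|1|2)
    span: int
    peptide_window: str
    probability: float

    @property
    def codon_start(self) -> int:
        return self.nt_offset // 3


def iter_window_slots(n_codons: int, motif_length: int):
    """All (codon_start, offset, span) slots fully inside a CDS of
    ``n_codons`` codons for a motif of the given length."""
    spans = [codon_span(motif_length, p) for p in (0, 1, 2)]
    for j in range(n_codons):
        for p, span in enumerate(spans):
            if j + span <= n_codons:
                yield j, p, span


def enumerate_potential_windows(
    cds: CodingSequence, motif: str, table: CodonNgramTable
) -> list[PotentialMotif]:
    """Every potential-motif window of one CDS (P_mot > 0), in position order.

    Unusable windows (peptide n-gram unobserved in the genome) are skipped.
    Probability lookups are cached per (peptide, offset) on the table, so a
    genome-wide scan costs O(total codons) cache hits.
    """
    motif = parse_motif(motif)
    out = []
    pep = cds.peptide
    for j, p, span in iter_window_slots(cds.n_codons, len(motif)):
        prob = motif_probability(pep[j : j + span], p, motif, table)
        if prob:
            out.append(
                PotentialMotif(
                    gene_id=cds.gene_id,
                    nt_offset=3 * j + p,
                    codon_offset=p,
                    span=span,
                    peptide_window=pep[j : j + span],
                    probability=prob,
                )
            )
    return out


class ProteomeIndex:
    """Peptide k-gram index over a set of coding sequences.

    Maps every in-frame peptide window (per span) to the list of
    (gene, codon position) occurrences, so that a motif scan evaluates
    P_mot once per *distinct* window peptide and emits all its positions —
    the indexed-search equivalent of a suffix-tree proteome scan, built in
    time linear in total proteome length.
    """

    def __init__(self, cds_list: list[CodingSequence], spans: list[int]):
        self.cds = {c.gene_id: c for c in cds_list}
        self.spans = sorted(set(spans))
        self.index: dict[int, dict[str, list[tuple[str, int]]]] = {}
        for span in self.spans:
            idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for cds in cds_list:
                pep = cds.peptide
                for j in range(len(pep) - span + 1):
                    idx[pep[j : j + span]].append((cds.gene_id, j))
            self.index[span] = dict(idx)

    @classmethod
    def for_motif_length(cls, cds_list: list[CodingSequence], motif_length: int):
        return cls(cds_list, [codon_span(motif_length, p) for p in (0, 1, 2)])

    def scan(self, motif: str, table: CodonNgramTable) -> dict[str, list[PotentialMotif]]:
        """Potential-motif windows for every gene, keyed by gene id.

        Identical result set to a naive per-gene, per-position scan.
        """
        motif = parse_motif(motif)
        hits: dict[str, list[PotentialMotif]] = {g: [] for g in self.cds}
        for p in (0, 1, 2):
            span = codon_span(len(motif), p)
            if span not in self.index:
                raise MotifError(f"index lacks span {span}; rebuild for this motif")
            for pep, positions in self.index[span].items():
                prob = motif_probability(pep, p, motif, table)
                if not prob:
                    continue
                for gene_id, j in positions:
                    hits[gene_id].append(
                        PotentialMotif(
                            gene_id=gene_id,
                            nt_offset=3 * j + p,
                            codon_offset=p,
                            span=span,
                            peptide_window=pep,
                            probability=prob,
                        )
                    )
        for lst in hits.values():
            lst.sort(key=lambda w: (w.nt_offset, w.codon_offset))
        return hits


def expand_iupac(motif: str) -> list[str]:
    """All concrete A/C/G/T expansions of an IUPAC motif."""
    motif = parse_motif(motif)
    pools = [sorted(_IUPAC[m]) for m in motif]
    return ["".join(c) for c in itertools.product(*pools)]
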