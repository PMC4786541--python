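"""Observed motif counts and per-gene / per-set motif profiles.

The observed count ``m`` of a gene is the number of potential-motif windows
whose realized nucleotides actually spell the motif. Counting is restricted
to usable windows so that the observed count and the Poisson-binomial
expectation are defined on the same event space. Strand handling: the
template-strand profile of a motif is the coding-strand profile of its
reverse complement; leading/lagging profiles pick coding or template per
gene according to its replication context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_model import (
    CodonNgramTable,
    PotentialMotif,
    ProteomeIndex,
    codon_span,
    enumerate_potential_windows,
    matches_at,
    parse_motif,
    reverse_complement,
)
from .genome_io import CodingSequence, ReplicationContext
from .stats import poisson_binomial_summary, zscore

STRAND_MODES = ("coding", "template", "leading", "lagging")


def effective_motif(motif: str, strand_mode: str, context: ReplicationContext | None = None) -> str:
    """The motif actually searched on the coding strand for a strand mode."""
    motif = parse_motif(motif)
    if strand_mode == "coding":
        return motif
    if strand_mode == "template":
        return reverse_complement(motif)
    if strand_mode in ("leading", "lagging"):
        if context is None:
            raise ValueError(f"strand mode {strand_mode!r} needs a ReplicationContext")
        on_coding = (context.strand_class == strand_mode)
        return motif if on_coding else reverse_complement(motif)
    raise ValueError(f"unknown strand mode {strand_mode!r}")


@dataclass(frozen=True)
class MotifProfile:
    """Motif statistics for one gene, gene set or chromosomal window.

    ``probabilities`` are the P_mot values of the usable potential-motif
    windows; ``m`` the observed count among them. ``m_bar = sum(P)`` and
    ``s = sqrt(sum(P(1-P)))`` are the Poisson-binomial moments and
    ``z = (m - m_bar) / s``. A scope with no usable windows has no z-score
    (``z is None``) — missing, deliberately never reported as 0.
    """

    scope_id: str
    motif: str
    strand_mode: str
    probabilities: tuple[float, ...]
    m: int

    def __post_init__(self):
        if self.m < 0 or self.m > len(self.probabilities):
            raise ValueError(
                f"{self.scope_id}: observed count {self.m} outside "
                f"[0, {len(self.probabilities)}]"
            )

    @property
    def n_windows(self) -> int:
        return len(self.probabilities)

    @property
    def m_bar(self) -> float:
        return poisson_binomial_summary(self.probabilities)[0]

    @property
    def s(self) -> float:
        return poisson_binomial_summary(self.probabilities)[1]

    @property
    def z(self) -> float | None:
        if not self.probabilities:
            return None
        m_bar, s = poisson_binomial_summary(self.probabilities)
        return zscore(self.m, m_bar, s)


def count_matches(
    cds: CodingSequence, windows: list[PotentialMotif], search_motif: str
) -> int:
    nt = cds.nucleotides
    return sum(1 for w in windows if matches_at(nt, w.nt_offset, search_motif))


def observed_count(
    cds: CodingSequence,
    motif: str,
    table: CodonNgramTable,
    strand_mode: str = "coding",
    context: ReplicationContext | None = None,
) -> int:
    """Observed motif count of one gene: realized matches among usable
    potential-motif windows on the requested strand."""
    search = effective_motif(motif, strand_mode, context)
    windows = enumerate_potential_windows(cds, search, table)
    return count_matches(cds, windows, search)


def gene_profile(
    cds: CodingSequence,
    motif: str,
    table: CodonNgramTable,
    strand_mode: str = "coding",
    context: ReplicationContext | None = None,
    _windows: list[PotentialMotif] | None = None,
) -> MotifProfile:
    """Per-gene motif profile (window probabilities, observed count, z)."""
    search = effective_motif(motif, strand_mode, context)
    windows = (
        _windows
        if _windows is not None
        else enumerate_potential_windows(cds, search, table)
    )
    return MotifProfile(
        scope_id=cds.gene_id,
        motif=parse_motif(motif),
        strand_mode=strand_mode,
        probabilities=tuple(w.probability for w in windows),
        m=count_matches(cds, windows, search),
    )


def merge_profiles(profiles: list[MotifProfile], scope_id: str = "set") -> MotifProfile:
    """Extend the model to a set of genes by merging the probability lists
    and summing observed counts; moments and z are recomputed on the merged
    list."""
    if not profiles:
        raise ValueError("cannot merge an empty list of profiles")
    motifs = {p.motif for p in profiles}
    modes = {p.strand_mode for p in profiles}
    if len(motifs) > 1 or len(modes) > 1:
        raise ValueError("profiles to merge must share motif and strand mode")
    probs: list[float] = []
    for p in profiles:
        probs.extend(p.probabilities)
    return MotifProfile(
        scope_id=scope_id,
        motif=motifs.pop(),
        strand_mode=modes.pop(),
        probabilities=tuple(probs),
        m=sum(p.m for p in profiles),
    )


def genome_scan(
    cds_list: list[CodingSequence],
    motif: str,
    table: CodonNgramTable,
    contexts: list[ReplicationContext] | None = None,
) -> pd.DataFrame:
    """Per-gene motif z-scores for the whole genome, coding and template
    strand, one row per gene.

    Uses the proteome index so each distinct peptide window is evaluated
    once. When replication contexts are given, their labels are attached as
    columns (``replichore``, ``strand_class``, ``half``), from which the
    leading/lagging z of a gene is ``z_coding`` if it lies on the leading
    strand and ``z_template`` otherwise.
    """
    motif = parse_motif(motif)
    index = ProteomeIndex.for_motif_length(cds_list, len(motif))
    ctx = {c.gene_id: c for c in contexts} if contexts else {}
    rows = []
    scans = {
        "coding": index.scan(motif, table),
        "template": index.scan(reverse_complement(motif), table),
    }
    for cds in cds_list:
        row: dict = {
            "gene_id": cds.gene_id,
            "start": cds.start,
            "end": cds.end,
            "strand": cds.strand,
            "midpoint": cds.midpoint,
        }
        c = ctx.get(cds.gene_id)
        row["replichore"] = c.replichore if c else None
        row["strand_class"] = c.strand_class if c else None
        row["half"] = c.half if c else None
        for mode in ("coding", "template"):
            search = motif if mode == "coding" else reverse_complement(motif)
            prof = gene_profile(
                cds, motif, table, strand_mode=mode,
                _windows=scans[mode][cds.gene_id],
            ) if mode == "coding" else MotifProfile(
                scope_id=cds.gene_id,
                motif=motif,
                strand_mode="template",
                probabilities=tuple(
                    w.probability for w in scans["template"][cds.gene_id]
                ),
                m=count_matches(cds, scans["template"][cds.gene_id], search),
            )
            row[f"n_windows_{mode}"] = prof.n_windows
            row[f"m_{mode}"] = prof.m
            row[f"m_bar_{mode}"] = prof.m_bar
            row[f"s_{mode}"] = prof.s
            row[f"z_{mode}"] = math.nan if prof.z is None else prof.z
        rows.append(row)
    return pd.DataFrame(rows)


def kmer_sweep(
    cds_list: list[CodingSequence],
    k: int,
    table: CodonNgramTable,
    per_gene: bool = False,
) -> pd.DataFrame:
    """z-scores of every concrete k-mer over a gene set.

    Shares the window enumeration across all 4^k motifs: for each distinct
    (peptide window, offset) the counts of every realizable k-mer are
    enumerated once, so a full tetramer sweep costs little more than a
    single-motif scan. By default returns one merged-set profile per k-mer
    (DataFrame indexed by k-mer with ``n_windows``, ``m``, ``m_bar``, ``s``,
    ``z``; z is NaN for k-mers with no usable window). With
    ``per_gene=True`` the statistics are kept per gene instead (long
    DataFrame with a ``gene_id`` column, only (gene, k-mer) pairs that have
    at least one usable window).

    Note: when the table is built from exactly this gene set, the merged-set
    expectation of every k-mer equals its observed count by construction
    (the frequencies come from the same windows), so set-level z-scores are
    ~0; per-gene and windowed scores carry the signal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    spans = {p: codon_span(k, p) for p in (0, 1, 2)}
    # cache[(pep, p)] = (den, {kmer: numerator})
    cache: dict[tuple[str, int], tuple[int, dict[str, int]]] = {}

    def window_stats(pep: str, p: int):
        key = (pep, p)
        hit = cache.get(key)
        if hit is not None:
            return hit
        from .codon_model import _codings  # internal enumeration helper

        den = 0
        nums: dict[str, int] = {}
        for cod in _codings(pep, table._back):
            w = table.count(cod)
            if w == 0:
                continue
            den += w
            kmer = cod[p : p + k]
            nums[kmer] = nums.get(kmer, 0) + w
        out = (den, nums)
        cache[key] = out
        return out

    def sweep_genes(genes):
        acc: dict[str, list] = {}  # kmer -> [n_windows, m, sum_p, sum_pq]
        for cds in genes:
            pep_full = cds.peptide
            nt = cds.nucleotides
            n_codons = cds.n_codons
            for j in range(n_codons):
                for p in (0, 1, 2):
                    span = spans[p]
                    if j + span > n_codons:
                        continue
                    den, nums = window_stats(pep_full[j : j + span], p)
                    if den == 0:
                        continue
                    start = 3 * j + p
                    realized = nt[start : start + k]
                    for kmer, num in nums.items():
                        prob = num / den
                        a = acc.get(kmer)
                        if a is None:
                            a = [0, 0, 0.0, 0.0]
                            acc[kmer] = a
                        a[0] += 1
                        a[2] += prob
                        a[3] += prob * (1.0 - prob)
                        if kmer == realized:
                            a[1] += 1
        return acc

    import itertools

    if per_gene:
        rows = []
        for cds in cds_list:
            for kmer, (n_windows, m, sum_p, sum_pq) in sweep_genes([cds]).items():
                s = math.sqrt(sum_pq)
                rows.append(
                    {"gene_id": cds.gene_id, "kmer": kmer, "n_windows": n_windows,
                     "m": m, "m_bar": sum_p, "s": s, "z": zscore(m, sum_p, s)}
                )
        return pd.DataFrame(rows)

    acc = sweep_genes(cds_list)
    rows = []
    for kmer in ("".join(c) for c in itertools.product("ACGT", repeat=k)):
        n_windows, m, sum_p, sum_pq = acc.get(kmer, (0, 0, 0.0, 0.0))
        s = math.sqrt(sum_pq)
        z = math.nan if n_windows == 0 else zscore(m, sum_p, s)
        rows.append(
            {"kmer": kmer, "n_windows": n_windows, "m": m, "m_bar": sum_p, "s": s, "z": z}
        )
    return pd.DataFrame(rows).set_index("kmer")
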