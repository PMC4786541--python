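"""Synthetic coding sequences and genomes with controlled motif content.

The generator emulates the randomized-sequence studies used to validate the
codon-redundancy model: random in-frame coding sequences of configurable
length carrying an exact number of potential-motif windows and an exact
number of realized motifs, whole artificial genomes whose per-gene
(potential, realized) counts match a reference table, and the tetramer
interdependence experiment (z-scores of all k-mers in genomes where one
k-mer is enriched).

"Potential" here is combinatorial: a window is potential when *some*
synonymous re-encoding of its peptide spells the motif, independent of any
frequency table. Construction draws a random peptide and codons, erases all
accidental potential windows, plants non-overlapping motif-permitting
peptides (realizing the motif in a chosen subset), then repairs until the
audit matches the targets exactly. Everything is deterministic per seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .codon_model import (
    CodonNgramTable,
    back_table,
    build_codon_ngram_table,
    codon_span,
    matches_at,
    parse_motif,
)
from .genome_io import CodingSequence, Replicon, make_coding_sequence
from .motif_engine import gene_profile, merge_profiles
from .stats import zscore

AA_ALPHABET = tuple(sorted(back_table(11)))  # 20 standard amino acids


class InfeasibleSpecError(RuntimeError):
    """Raised when the requested (length, counts) cannot be constructed."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Targets for one random coding sequence.

    ``n_potential`` counts potential-motif windows, ``n_real`` the realized
    motifs among them (n_real <= n_potential). ``codon_source`` controls the
    background codon draw: uniform over synonymous codons, or weighted by a
    genome table's codon usage.
    """

    length: int = 3000
    motif: str = "GATC"
    n_potential: int = 0
    n_real: int = 0
    codon_source: str = "uniform"  # uniform | table
    seed: int | None = None

    def __post_init__(self):
        if self.length < 6 or self.length % 3:
            raise InfeasibleSpecError("length must be a positive multiple of 3")
        if not 0 <= self.n_real <= self.n_potential:
            raise InfeasibleSpecError("need 0 <= n_real <= n_potential")
        if self.codon_source not in ("uniform", "table"):
            raise InfeasibleSpecError(f"unknown codon source {self.codon_source!r}")
        parse_motif(self.motif)


def _translate(codons: list[str], translation_table: int = 11) -> str:
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[translation_table]
    out = []
    for i, cod in enumerate(codons):
        aa = tab.forward_table[cod]
        if i == 0 and cod in tab.start_codons:
            aa = "M"
        out.append(aa)
    return "".join(out)


@lru_cache(maxsize=64)
def _catalogue(motif: str, p: int, translation_table: int = 11):
    """Peptides admitting ``motif`` at in-codon offset ``p``.

    Returns {peptide: (clean_with, clean_without)} where clean_with are
    codon strings realizing the motif at offset p and nowhere else in the
    window, clean_without realize it nowhere, and the peptide hosts no
    *other* potential sub-window inside the same codon range (so a planted
    window contributes exactly one potential position).
    """
    motif = parse_motif(motif)
    l = len(motif)
    span = codon_span(l, p)
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[translation_table]
    stops = set(tab.stop_codons)
    fwd = tab.forward_table
    back = back_table(translation_table)

    # discover admitting peptides by fixing the motif bases and freeing the rest
    from .codon_model import expand_iupac

    peps: set[str] = set()
    n_nt = 3 * span
    for concrete in expand_iupac(motif):
        free = [i for i in range(n_nt) if not (p <= i < p + l)]
        for fill in itertools.product("ACGT", repeat=len(free)):
            s = [""] * n_nt
            for i, b in zip(range(p, p + l), concrete):
                s[i] = b
            for i, b in zip(free, fill):
                s[i] = b
            cods = ["".join(s[i : i + 3]) for i in range(0, n_nt, 3)]
            if any(c in stops for c in cods):
                continue
            peps.add("".join(fwd[c] for c in cods))

    # offsets of other windows that fit entirely inside the planted range
    other_offsets = [o for o in range(0, n_nt - l + 1) if o != p]

    out = {}
    for pep in sorted(peps):
        # reject peptides with another potential sub-window in the range
        internal = False
        for o in other_offsets:
            p2, dj = o % 3, o // 3
            span2 = codon_span(l, p2)
            if dj + span2 <= span and _is_potential(pep[dj : dj + span2], p2, motif,
                                                   translation_table):
                internal = True
                break
        if internal:
            continue
        clean_with, clean_without = [], []
        for combo in itertools.product(*[back[aa] for aa in pep]):
            cod = "".join(combo)
            hits = [o for o in range(0, n_nt - l + 1) if matches_at(cod, o, motif)]
            if hits == [p]:
                clean_with.append(cod)
            elif not hits:
                clean_without.append(cod)
        if clean_with:
            out[pep] = (tuple(clean_with), tuple(clean_without))
    return out


@lru_cache(maxsize=2_000_000)
def _is_potential(pep: str, p: int, motif: str, translation_table: int = 11) -> bool:
    """True when some synonymous encoding of ``pep`` spells the motif at
    offset ``p`` (combinatorial, table-free)."""
    back = back_table(translation_table)
    for combo in itertools.product(*[back[aa] for aa in pep]):
        if matches_at("".join(combo), p, parse_motif(motif)):
            return True
    return False


def audit_motif_content(nucleotides: str, motif: str, translation_table: int = 11):
    """Combinatorial (potential, realized) window sets of a coding sequence.

    Returns two sets of (codon_start, offset) keys; realized is a subset of
    potential by construction.
    """
    motif = parse_motif(motif)
    l = len(motif)
    codons = [nucleotides[i : i + 3] for i in range(0, len(nucleotides), 3)]
    pep = _translate(codons, translation_table)
    n = len(codons)
    potential, realized = set(), set()
    for p in (0, 1, 2):
        span = codon_span(l, p)
        for j in range(n - span + 1):
            if _is_potential(pep[j : j + span], p, motif, translation_table):
                potential.add((j, p))
                if matches_at(nucleotides, 3 * j + p, motif):
                    realized.add((j, p))
    return potential, realized


class _Background:
    """Seeded draw of background amino acids and codons."""

    def __init__(self, rng, codon_source: str, table: CodonNgramTable | None,
                 translation_table: int = 11):
        self.rng = rng
        back = back_table(translation_table)
        self.aas = AA_ALPHABET
        self.codons = {}
        self.weights = {}
        for aa in self.aas:
            cods = back[aa]
            if codon_source == "table":
                if table is None:
                    raise InfeasibleSpecError("table-driven codon source needs a table")
                w = np.array([table.counts[1].get(c, 0) for c in cods], dtype=float)
                if w.sum() == 0:
                    w = np.ones(len(cods))
            else:
                w = np.ones(len(cods))
            self.codons[aa] = cods
            self.weights[aa] = w / w.sum()

    def draw_aa(self, exclude: str | None = None) -> str:
        while True:
            aa = self.aas[self.rng.integers(len(self.aas))]
            if aa != exclude:
                return aa

    def draw_codon(self, aa: str) -> str:
        cods, w = self.codons[aa], self.weights[aa]
        return cods[self.rng.choice(len(cods), p=w)]


def random_coding_sequence(
    spec: SyntheticSpec,
    table: CodonNgramTable | None = None,
    gene_id: str = "synth_gene",
    translation_table: int = 11,
    max_restarts: int = 30,
    max_sweeps: int = 80,
) -> CodingSequence:
    """Random CDS with exactly ``n_potential`` potential-motif windows and
    ``n_real`` realized motifs, deterministic per seed.

    Raises :class:`InfeasibleSpecError` when the targets cannot be reached
    within bounded attempts (e.g. too many windows for the length).
    """
    motif = parse_motif(spec.motif)
    l = len(motif)
    n_codons = spec.length // 3
    spans = {p: codon_span(l, p) for p in (0, 1, 2)}
    max_span = max(spans.values())
    # each planted window needs its codons plus a one-codon gap; codon 0 is ATG
    if spec.n_potential * (max_span + 1) > n_codons - 2:
        raise InfeasibleSpecError(
            f"{spec.n_potential} windows of up to {max_span} codons do not fit "
            f"in {n_codons} codons"
        )
    cats = {p: _catalogue(motif, p, translation_table) for p in (0, 1, 2)}
    if all(not c for c in cats.values()):
        raise InfeasibleSpecError(f"motif {motif} admits no coding window")
    rng = np.random.default_rng(spec.seed)
    bg = _Background(rng, spec.codon_source, table, translation_table)

    for _ in range(max_restarts):
        codons = ["ATG"] + [bg.draw_codon(bg.draw_aa()) for _ in range(n_codons - 1)]

        # ---- plant non-overlapping windows with one-codon gaps
        occupied = np.zeros(n_codons, dtype=bool)
        occupied[0] = True
        planted: list[tuple[int, int]] = []
        tries = 0
        while len(planted) < spec.n_potential and tries < 50 * max(spec.n_potential, 1):
            tries += 1
            p = int(rng.integers(3))
            if not cats[p]:
                continue
            span = spans[p]
            j = int(rng.integers(1, n_codons - span + 1))
            lo, hi = max(j - 1, 0), min(j + span + 1, n_codons)
            if occupied[lo:hi].any():
                continue
            occupied[j : j + span] = True
            planted.append((j, p))
        if len(planted) < spec.n_potential:
            continue  # restart with a fresh layout
        order = rng.permutation(len(planted))
        realized_set = {planted[i] for i in order[: spec.n_real]}
        ok = True
        for (j, p) in planted:
            cat = cats[p]
            peps = sorted(cat)
            want_real = (j, p) in realized_set
            choices = [
                pep for pep in peps if (cat[pep][0] if want_real else cat[pep][1])
            ]
            if not choices:
                ok = False
                break
            pep = choices[int(rng.integers(len(choices)))]
            pool = cat[pep][0] if want_real else cat[pep][1]
            cod = pool[int(rng.integers(len(pool)))]
            for t in range(spans[p]):
                codons[j + t] = cod[3 * t : 3 * t + 3]
        if not ok:
            continue

        planted_set = set(planted)
        in_planted = occupied.copy()

        # ---- repair: erase accidental potential windows outside the plan
        done = False
        for _sweep in range(max_sweeps):
            nt = "".join(codons)
            potential, realized = audit_motif_content(nt, motif, translation_table)
            if potential == planted_set and realized == realized_set:
                done = True
                break
            extras = potential - planted_set
            if not extras:
                break  # planted window broken: restart
            for (j, p) in extras:
                span = spans[p]
                free = [c for c in range(j, j + span) if not in_planted[c]]
                if not free:
                    break
                c = free[int(rng.integers(len(free)))]
                # substitute the amino acid until this window stops being potential
                pepw = None
                for _ in range(40):
                    aa = bg.draw_aa()
                    codons[c] = bg.draw_codon(aa)
                    peps = _translate(codons[j : j + span], translation_table)
                    if not _is_potential(peps, p, motif, translation_table):
                        pepw = peps
                        break
                if pepw is None:
                    break
        if done:
            nt = "".join(codons)
            return CodingSequence(
                gene_id=gene_id,
                start=0,
                end=len(nt),
                strand="+",
                nucleotides=nt,
                peptide=_translate(codons, translation_table),
                midpoint=len(nt) // 2,
            )
    raise InfeasibleSpecError(
        f"could not construct spec {spec} within {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class SyntheticGenome:
    """A generated replicon with its genes and serialized FASTA/GFF3."""

    replicon: Replicon
    cds_list: list[CodingSequence]
    fasta: str
    gff: str
    skipped: list[tuple[str, str]]

    def write(self, fasta_path, gff_path) -> None:
        with open(fasta_path, "w") as fh:
            fh.write(self.fasta)
        with open(gff_path, "w") as fh:
            fh.write(self.gff)


def assemble_genome(
    gene_sequences: list[str],
    gene_ids: list[str],
    strands: list[str] | None = None,
    spacer: int = 30,
    ori_position: int = 0,
    ter_position: int | None = None,
    replicon_id: str = "synth_replicon",
    seed: int | None = None,
    skipped: list[tuple[str, str]] | None = None,
) -> SyntheticGenome:
    """Lay coding sequences (given on their coding strand, stop codon absent)
    onto a circular replicon with random intergenic spacers, appending a TAA
    stop to each; minus-strand genes are reverse-complemented into the
    forward sequence. Returns the replicon, re-extracted validated CDSs and
    FASTA/GFF3 text.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    strands = strands or ["+"] * len(gene_sequences)
    parts, feats = [], []
    pos = 0
    for nt, gid, strand in zip(gene_sequences, gene_ids, strands):
        sp = "".join("ACGT"[i] for i in rng.integers(4, size=spacer))
        parts.append(sp)
        pos += spacer
        genomic = nt + "TAA"
        if strand == "-":
            genomic = str(Seq(genomic).reverse_complement())
        parts.append(genomic)
        feats.append((gid, pos, pos + len(genomic), strand))
        pos += len(genomic)
    parts.append("".join("ACGT"[i] for i in rng.integers(4, size=spacer)))
    sequence = "".join(parts)
    replicon = Replicon(
        id=replicon_id,
        sequence=sequence,
        topology="circular",
        ori_position=ori_position,
        ter_position=ter_position,
    )
    cds_list = [
        make_coding_sequence(gid, s, e, strand, sequence)
        for gid, s, e, strand in feats
    ]
    fasta_lines = [f">{replicon_id}"]
    fasta_lines += [sequence[i : i + 70] for i in range(0, len(sequence), 70)]
    gff_lines = ["##gff-version 3"]
    for gid, s, e, strand in feats:
        gff_lines.append(
            f"{replicon_id}\tdistamo_synth\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
            f"ID={gid};locus_tag={gid}"
        )
    return SyntheticGenome(
        replicon=replicon,
        cds_list=cds_list,
        fasta="\n".join(fasta_lines) + "\n",
        gff="\n".join(gff_lines) + "\n",
        skipped=skipped or [],
    )


def random_gene(
    n_codons: int, rng, gene_id: str = "gene", codon_source: str = "uniform",
    table: CodonNgramTable | None = None,
) -> str:
    """Plain random in-frame coding sequence (no count control), as coding-
    strand nucleotides without stop codon."""
    bg = _Background(rng, codon_source, table)
    codons = ["ATG"] + [bg.draw_codon(bg.draw_aa()) for _ in range(n_codons - 1)]
    return "".join(codons)


def random_codon_corpus(
    n_genes: int, n_codons: int, seed: int | None = None, gene_prefix: str = "bg",
) -> list[CodingSequence]:
    """Bulk-generated plain random coding sequences (uniform amino acids,
    uniform synonymous codons, ATG start).

    Vectorized so that genome-scale null-table corpora (hundreds of
    thousands of codons, the scale at which the frequency-based P_mot
    estimates are well calibrated) are cheap to produce.
    """
    rng = np.random.default_rng(seed)
    back = back_table(11)
    n_syn = np.array([len(back[aa]) for aa in AA_ALPHABET])
    all_codons = np.array([c for aa in AA_ALPHABET for c in back[aa]])
    offsets = np.concatenate([[0], np.cumsum(n_syn)])[:-1]
    per_gene = n_codons - 1
    aa_idx = rng.integers(len(AA_ALPHABET), size=n_genes * per_gene)
    syn_idx = rng.integers(n_syn[aa_idx])
    codons = all_codons[offsets[aa_idx] + syn_idx]
    aa_letters = np.array(list(AA_ALPHABET))[aa_idx]
    genes = []
    for g in range(n_genes):
        sl = slice(g * per_gene, (g + 1) * per_gene)
        nt = "ATG" + "".join(codons[sl])
        genes.append(
            CodingSequence(
                gene_id=f"{gene_prefix}{g:05d}", start=0, end=len(nt), strand="+",
                nucleotides=nt, peptide="M" + "".join(aa_letters[sl]),
                midpoint=len(nt) // 2,
            )
        )
    return genes


def resample_genome_like(
    reference_counts: pd.DataFrame,
    motif: str,
    seed: int | None = None,
    default_length: int = 900,
    **genome_kwargs,
) -> SyntheticGenome:
    """Synthetic genome whose per-gene (potential, realized) counts for
    ``motif`` match a reference table.

    ``reference_counts`` needs columns ``gene_id``, ``n_potential``,
    ``n_real`` and optionally ``length`` (bp, default 900). Genes with
    infeasible targets are skipped and listed in ``skipped``.
    """
    rng = np.random.default_rng(seed)
    seqs, ids, skipped = [], [], []
    for row in reference_counts.itertuples(index=False):
        length = int(getattr(row, "length", default_length) or default_length)
        sub = int(rng.integers(2**31 - 1))
        try:
            spec = SyntheticSpec(
                length=length, motif=motif,
                n_potential=int(row.n_potential), n_real=int(row.n_real), seed=sub,
            )
            cds = random_coding_sequence(spec, gene_id=str(row.gene_id))
        except InfeasibleSpecError as exc:
            skipped.append((str(row.gene_id), str(exc)))
            continue
        seqs.append(cds.nucleotides)
        ids.append(cds.gene_id)
    return assemble_genome(
        seqs, ids, seed=int(rng.integers(2**31 - 1)), skipped=skipped, **genome_kwargs
    )


def leading_bias_genome(
    motif: str = "GGCAAT",
    n_genes: int = 30,
    gene_length: int = 900,
    n_potential: int = 12,
    n_real_enriched: int = 11,
    n_real_baseline: int = 3,
    enrich: bool = True,
    seed: int | None = None,
) -> SyntheticGenome:
    """Circular fixture genome with the motif planted preferentially into the
    coding sequences of leading-strand genes (or uniformly when ``enrich``
    is False).

    Genes alternate strands on both replichores so leading and lagging
    classes are balanced; ori sits at position 0 and ter opposite.
    """
    rng = np.random.default_rng(seed)
    seqs, ids, strands = [], [], []
    for g in range(n_genes):
        right = g < n_genes // 2  # first half of the circle: right replichore
        strand = ("+" if g % 2 == 0 else "-") if right else ("-" if g % 2 == 0 else "+")
        leading = (right and strand == "+") or (not right and strand == "-")
        n_real = (
            n_real_enriched if (enrich and leading) else n_real_baseline
        )
        spec = SyntheticSpec(
            length=gene_length, motif=motif, n_potential=n_potential,
            n_real=n_real, seed=int(rng.integers(2**31 - 1)),
        )
        cds = random_coding_sequence(spec, gene_id=f"g{g:03d}")
        seqs.append(cds.nucleotides)
        ids.append(cds.gene_id)
        strands.append(strand)
    return assemble_genome(
        seqs, ids, strands=strands, ori_position=0,
        seed=int(rng.integers(2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# null resampling and interdependence


def codon_resample_null(
    cds: CodingSequence,
    motif: str,
    table: CodonNgramTable,
    n_replicates: int = 2000,
    seed: int | None = None,
) -> np.ndarray:
    """z-scores of a gene under the codon null: codons are re-drawn per the
    table's synonymous-codon frequencies (peptide fixed), and the observed
    count over the gene's usable windows is re-scored each time.

    Window positions and probabilities do not change (the peptide is
    fixed), so each replicate only re-counts realized motifs.
    """
    from .codon_model import enumerate_potential_windows

    motif = parse_motif(motif)
    rng = np.random.default_rng(seed)
    windows = enumerate_potential_windows(cds, motif, table)
    if not windows:
        raise ValueError(f"gene {cds.gene_id} has no usable windows for {motif}")
    probs = np.array([w.probability for w in windows])
    m_bar = float(probs.sum())
    s = math.sqrt(float((probs * (1 - probs)).sum()))
    pep = cds.peptide
    n = len(pep)
    # draw codon indices per position, grouped by amino acid
    codon_choice = np.empty((n_replicates, n), dtype=np.int8)
    groups: dict[str, list[int]] = {}
    for i, aa in enumerate(pep):
        groups.setdefault(aa, []).append(i)
    cods_by_aa = {}
    for aa, idx in groups.items():
        cods, w = table.codon_weights(aa)
        w = np.asarray(w, dtype=float)
        if w.sum() == 0:
            w = np.ones(len(cods))
        w = w / w.sum()
        cods_by_aa[aa] = cods
        codon_choice[:, idx] = rng.choice(
            len(cods), size=(n_replicates, len(idx)), p=w
        )
    z = np.empty(n_replicates)
    win_keys = [(w.nt_offset, w.span, w.codon_offset) for w in windows]
    for r in range(n_replicates):
        row = codon_choice[r]
        nt = "".join(cods_by_aa[aa][row[i]] for i, aa in enumerate(pep))
        m = sum(1 for off, span, p in win_keys if matches_at(nt, off, motif))
        z[r] = zscore(m, m_bar, s)
    return z


def coupling_experiment(
    motif: str = "GATC",
    partners: tuple[str, ...] = ("AGAT", "AATC"),
    n_genes: int = 12,
    gene_length: int = 1500,
    n_potential: int = 25,
    n_real: int = 25,
    control_genes: int = 150,
    seed: int | None = None,
) -> dict[str, float]:
    """Merged-set z of partner motifs in genes extremely enriched for
    ``motif``, scored against a frequency table from an unenriched control
    pool of the same background.

    Probes the mechanistic coupling between overlapping motifs (e.g. AGAT
    rides along with GATC) and competing motifs that share potential sites
    (e.g. AATC loses to GATC).
    """
    rng = np.random.default_rng(seed)
    control = [
        CodingSequence(
            gene_id=f"ctrl{i}", start=0, end=gene_length, strand="+",
            nucleotides=(nt := random_gene(gene_length // 3, rng)),
            peptide=_translate([nt[j : j + 3] for j in range(0, len(nt), 3)]),
            midpoint=gene_length // 2,
        )
        for i in range(control_genes)
    ]
    max_span = max(
        codon_span(len(m), p) for m in (motif, *partners) for p in (0, 1, 2)
    )
    table = build_codon_ngram_table(control, max_span)
    genes = [
        random_coding_sequence(
            SyntheticSpec(
                length=gene_length, motif=motif, n_potential=n_potential,
                n_real=n_real, seed=int(rng.integers(2**31 - 1)),
            ),
            gene_id=f"enr{i}",
        )
        for i in range(n_genes)
    ]
    out = {}
    for m in (motif, *partners):
        prof = merge_profiles(
            [gene_profile(g, m, table) for g in genes], scope_id="enriched_set"
        )
        out[m] = prof.z
    return out


def interdependence_experiment(
    k: int = 4,
    n_genomes: int = 6,
    genes_per_genome: int = 25,
    gene_length: int = 900,
    enriched_gene_fraction: float = 0.25,
    boost_sigma: float = 3.0,
    seed: int | None = None,
) -> dict:
    """Scaled-down k-mer interdependence study on per-gene z-score pairs.

    For each of ``n_genomes`` artificial genomes one k-mer is enriched at a
    biological level: a fraction of the genes carry extra realized copies
    (about ``boost_sigma`` per-gene standard deviations above expectation,
    capacity permitting) while per-gene counts otherwise match plain random
    genes; a matched control genome per enriched genome is left untouched.
    Every genome is scored for all 4^k k-mers per gene against its own
    frequency table — the whole-genome set score is identically ~0 by the
    self-calibration of the null model, so the informative unit is the gene.

    The conditional probability that another k-mer is significant in a gene
    where the enriched k-mer is significant is compared with the marginal
    significance probability of k-mers in control genes. Returns a dict
    with the per-(gene, k-mer) pair table and the two probabilities with
    Monte-Carlo standard errors.
    """
    from .motif_engine import kmer_sweep

    rng = np.random.default_rng(seed)
    all_kmers = ["".join(c) for c in itertools.product("ACGT", repeat=k)]
    enriched = [all_kmers[i] for i in rng.choice(len(all_kmers), n_genomes, replace=False)]
    n_codons = gene_length // 3
    records = []

    def natural_counts(motif):
        rows = []
        for i in range(genes_per_genome):
            nt = random_gene(n_codons, rng, gene_id=f"g{i}")
            pot, real = audit_motif_content(nt, motif)
            rows.append({"gene_id": f"g{i:03d}", "n_potential": len(pot),
                         "n_real": len(real), "length": gene_length})
        return pd.DataFrame(rows)

    for gi, motif1 in enumerate(enriched):
        for enrich in (True, False):
            ref = natural_counts(motif1)
            boosted: set[str] = set()
            if enrich:
                n_boost = max(2, round(enriched_gene_fraction * len(ref)))
                for idx in rng.permutation(len(ref))[:n_boost]:
                    real = int(ref.iloc[idx]["n_real"])
                    pot = int(ref.iloc[idx]["n_potential"])
                    extra = math.ceil(boost_sigma * math.sqrt(max(real, 1)) + 1)
                    ref.iloc[idx, ref.columns.get_loc("n_real")] = min(
                        pot, real + extra
                    )
                    boosted.add(str(ref.iloc[idx]["gene_id"]))
            genome = resample_genome_like(
                ref, motif1, seed=int(rng.integers(2**31 - 1)),
                replicon_id=f"sim{gi}_{'enr' if enrich else 'ctl'}",
            )
            table = build_codon_ngram_table(
                genome.cds_list, max(codon_span(k, p) for p in (0, 1, 2))
            )
            sweep = kmer_sweep(genome.cds_list, k, table, per_gene=True)
            sweep["genome"] = genome.replicon.id
            sweep["enriched_motif"] = motif1
            sweep["planted"] = enrich
            sweep["boosted_gene"] = sweep["gene_id"].isin(boosted)
            records.append(sweep)
    pairs = pd.concat(records, ignore_index=True)
    pairs["is_enriched_motif"] = pairs["kmer"] == pairs["enriched_motif"]

    finite = pairs[np.isfinite(pairs["z"])]
    enr = finite[finite["planted"]]
    sig_genes = enr[enr["is_enriched_motif"] & (enr["z"].abs() >= 2)][
        ["genome", "gene_id"]
    ]
    keys = set(map(tuple, sig_genes.to_numpy()))
    cond = enr[
        ~enr["is_enriched_motif"]
        & enr.apply(lambda r: (r["genome"], r["gene_id"]) in keys, axis=1)
    ]
    marg = finite[~finite["planted"] & ~finite["is_enriched_motif"]]
    p_cond = float((cond["z"].abs() >= 2).mean()) if len(cond) else math.nan
    p_marg = float((marg["z"].abs() >= 2).mean()) if len(marg) else math.nan

    def se(p, n):
        return math.sqrt(max(p * (1 - p), 1.0 / max(n, 1)) / n) if n else math.nan

    return {
        "pairs": pairs,
        "p_conditional": p_cond,
        "p_marginal": p_marg,
        "se_conditional": se(p_cond, len(cond)),
        "se_marginal": se(p_marg, len(marg)),
        "n_conditional": int(len(cond)),
        "n_marginal": int(len(marg)),
        "n_significant_enriched_genes": int(len(sig_genes)),
    }
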