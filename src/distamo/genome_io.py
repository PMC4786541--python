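"""Genome input: sequence + annotation reading, CDS validation, replication context.

Coordinates are 0-based half-open on the forward strand throughout the
package; GFF3's 1-based closed intervals are converted on read. A coding
sequence that wraps past the end of a circular replicon is represented with
``end > replicon.length`` (``end - start`` is always the physical length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


class GenomeError(ValueError):
    """Raised for malformed genome input or inapplicable context operations."""


def _table(translation_table: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[translation_table]


@dataclass(frozen=True)
class Replicon:
    """One chromosome or plasmid with its replication landmarks.

    ``ter_position`` defaults to the point diametrically opposite the origin,
    the convention used when the terminus (dif site) is not supplied.
    """

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    ori_position: int | None = None
    ter_position: int | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.topology not in ("circular", "linear"):
            raise GenomeError(f"unknown topology {self.topology!r}")
        if self.ori_position is not None:
            if not 0 <= self.ori_position < len(seq):
                raise GenomeError(
                    f"ori_position {self.ori_position} outside sequence "
                    f"of length {len(seq)}"
                )
            if self.ter_position is None:
                object.__setattr__(
                    self, "ter_position", (self.ori_position + len(seq) // 2) % len(seq)
                )
            elif not 0 <= self.ter_position < len(seq):
                raise GenomeError(
                    f"ter_position {self.ter_position} outside sequence"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: in-frame coding-strand nucleotides and translation.

    ``nucleotides`` always reads 5'->3' on the coding strand (start codon
    first) with the trailing stop codon removed; ``peptide`` is its
    translation, with alternative start codons rendered as Met.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    nucleotides: str
    peptide: str
    midpoint: int

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]


@dataclass(frozen=True)
class ReplicationContext:
    """Replication-fork context labels for one gene."""

    gene_id: str
    replichore: str  # left | right
    strand_class: str  # leading | lagging
    half: str  # ori | ter


@dataclass
class ValidationReport:
    """Excluded CDSs and why; written as a two-column TSV."""

    excluded: list[tuple[str, str]] = field(default_factory=list)

    def add(self, gene_id: str, reason: str) -> None:
        self.excluded.append((gene_id, reason))

    def to_tsv(self) -> str:
        lines = ["gene_id\treason"]
        lines += [f"{g}\t{r}" for g, r in self.excluded]
        return "\n".join(lines) + "\n"


def circular_midpoint(start: int, end: int, length: int) -> int:
    """Midpoint of a (possibly origin-straddling) interval, modulo length."""
    return (start + (end - start) // 2) % length


def _extract(sequence: str, start: int, end: int, strand: str) -> str:
    L = len(sequence)
    if end <= L:
        sub = sequence[start:end]
    else:  # wraps past the circular origin of coordinates
        sub = sequence[start:] + sequence[: end - L]
    if strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


def make_coding_sequence(
    gene_id: str,
    start: int,
    end: int,
    strand: str,
    replicon_sequence: str,
    translation_table: int = 11,
) -> CodingSequence:
    """Extract, validate and translate one CDS; raises GenomeError on failure.

    Validation: length a positive multiple of 3, A/C/G/T only, no internal
    stop codons. A trailing stop codon is trimmed; the first codon is
    translated as Met when it is a start codon of the translation table.
    """
    nt = _extract(replicon_sequence, start, end, strand).upper()
    if len(nt) == 0 or len(nt) % 3 != 0:
        raise GenomeError("length not multiple of 3")
    if not set(nt) <= VALID_BASES:
        raise GenomeError("ambiguous nucleotide")
    tab = _table(translation_table)
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if codons[-1] in tab.stop_codons:
        codons = codons[:-1]
        nt = nt[:-3]
    if not codons:
        raise GenomeError("empty after stop trim")
    aas = []
    for i, cod in enumerate(codons):
        if cod in tab.stop_codons:
            raise GenomeError("internal stop codon")
        aa = tab.forward_table[cod]
        if i == 0 and cod in tab.start_codons:
            aa = "M"
        aas.append(aa)
    return CodingSequence(
        gene_id=gene_id,
        start=start,
        end=end,
        strand=strand,
        nucleotides=nt,
        peptide="".join(aas),
        midpoint=circular_midpoint(start, end, len(replicon_sequence)),
    )


def read_genome(
    fasta_path,
    gff_path,
    ori_position: int | None = None,
    ter_position: int | None = None,
    topology: str = "circular",
    translation_table: int = 11,
):
    """Read one replicon (FASTA) and its CDS annotation (GFF3).

    Returns ``(replicon, cds_list, report)``. CDS features are matched to the
    single FASTA record by seqid; gene ids come from the ``locus_tag``
    attribute, falling back to ``ID``. Minus-strand CDSs are
    reverse-complemented so that ``nucleotides`` reads on the coding strand.
    CDSs failing validation are excluded and listed in the report.
    """
    import gffutils

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise GenomeError(
            f"expected exactly one FASTA record, found {len(records)} "
            f"in {fasta_path}; analyze replicons one at a time"
        )
    rec = records[0]
    replicon = Replicon(
        id=rec.id,
        sequence=str(rec.seq),
        topology=topology,
        ori_position=ori_position,
        ter_position=ter_position,
    )

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    cds_list: list[CodingSequence] = []
    report = ValidationReport()
    n_seen = 0
    for feat in db.features_of_type("CDS", order_by=("start",)):
        n_seen += 1
        gene_id = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [
            f"CDS_{n_seen}"
        ])[0]
        if feat.seqid != replicon.id:
            report.add(gene_id, f"seqid {feat.seqid!r} does not match FASTA record")
            continue
        start = feat.start - 1  # GFF3 1-based closed -> 0-based half-open
        end = feat.end
        strand = feat.strand if feat.strand in "+-" else "+"
        try:
            cds = make_coding_sequence(
                gene_id, start, end, strand, replicon.sequence, translation_table
            )
        except GenomeError as exc:
            report.add(gene_id, str(exc))
            continue
        cds_list.append(cds)
    log.info(
        "read %s: %d CDS retained, %d excluded", replicon.id, len(cds_list),
        len(report.excluded),
    )
    return replicon, cds_list, report


def _circ_dist(a: int, b: int, length: int) -> int:
    d = (a - b) % length
    return min(d, length - d)


def assign_replication_context(
    replicon: Replicon, cds_list: list[CodingSequence]
) -> list[ReplicationContext]:
    """Label every gene by replichore, leading/lagging class and ori/ter half.

    The *right* replichore is the arc from ori to ter in ascending
    coordinates (circular); a gene is *leading* when its coding strand is the
    continuously synthesized strand of its replichore, i.e. (+ on the right)
    or (- on the left). A gene belongs to the *ori* half when its midpoint is
    circularly closer to ori than to ter (ties go to ori).
    """
    if replicon.topology != "circular":
        raise GenomeError(
            "replication-context analysis requires a circular replicon; "
            f"{replicon.id} is {replicon.topology}"
        )
    if replicon.ori_position is None:
        raise GenomeError("replication-context analysis requires an ori position")
    L = replicon.length
    ori, ter = replicon.ori_position, replicon.ter_position
    right_arc = (ter - ori) % L
    out = []
    for cds in cds_list:
        mid = cds.midpoint
        replichore = "right" if (mid - ori) % L < right_arc else "left"
        leading = (replichore == "right") == (cds.strand == "+")
        half = "ori" if _circ_dist(mid, ori, L) <= _circ_dist(mid, ter, L) else "ter"
        out.append(
            ReplicationContext(
                gene_id=cds.gene_id,
                replichore=replichore,
                strand_class="leading" if leading else "lagging",
                half=half,
            )
        )
    return out
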