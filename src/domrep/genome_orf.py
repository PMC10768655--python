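"""Open reading frame extraction and six-frame translation.

The first stage of the domain-repertoire pipeline turns each genomic
nucleotide sequence into the set of proteins it could encode: every reading
frame on both strands is scanned for ATG-initiated, stop-terminated ORFs,
which are translated with the standard genetic code and written out as a
per-organism protein FASTA ready for profile-HMM scanning.

Coordinates are always 0-based half-open on the forward strand, regardless of
the strand the ORF lies on; for minus-strand ORFs ``nt_seq`` is the reverse
complement of the forward-strand slice.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "OpenReadingFrame",
    "ProteinSequence",
    "read_fasta",
    "reverse_complement",
    "translate",
    "find_orfs",
    "write_protein_fasta",
]

# IUPAC nucleotide complements (uppercase); N and degenerate codes map to
# their complements, anything else is rejected.
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # TAA, TAG, TGA
_START_CODON = "ATG"


@dataclass(frozen=True)
class GenomeSequence:
    """One genomic nucleotide sequence (an accession from a genome databank)."""

    id: str
    organism: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ATG..stop span in one of the six reading frames.

    ``start``/``end`` are forward-strand, 0-based half-open and include the
    stop codon; ``frame`` is the offset (0..2) on the reading strand.
    """

    genome_id: str
    strand: str  # '+' or '-'
    frame: int
    start: int
    end: int
    nt_seq: str

    @property
    def orf_id(self) -> str:
        return f"{self.genome_id}|{self.strand}|{self.frame}|{self.start}"


@dataclass(frozen=True)
class ProteinSequence:
    """Translation of one ORF (stop codon excluded)."""

    orf_id: str
    aa_seq: str

    @property
    def length(self) -> int:
        return len(self.aa_seq)


def read_fasta(stream: TextIO | str, organism: str = "") -> list[GenomeSequence]:
    """Read FASTA text into :class:`GenomeSequence` records.

    The id is the header token before the first whitespace; sequences are
    uppercased with whitespace stripped. Raises ``ValueError`` on an empty
    file, sequence data before any header, or duplicate ids.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    stripped = text.lstrip()
    if not stripped:
        raise ValueError("empty FASTA input")
    if not stripped.startswith(">"):
        raise ValueError("sequence data before any FASTA header")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(id=rec.id, organism=organism, seq=str(rec.seq).upper()))
    return records


def reverse_complement(nt: str) -> str:
    """Reverse complement with IUPAC degenerate codes (N -> N)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(nt.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC nucleotide character {exc.args[0]!r}") from None


def translate(nt: str, table: int = 1) -> str:
    """Translate an in-frame nucleotide string to amino acids.

    Any codon containing a character outside {A,C,G,T} translates to ``X``
    (ambiguity codes are never resolved). A trailing stop codon is excluded
    from the output. Raises ``ValueError`` if the length is not a multiple
    of 3.
    """
    nt = nt.upper()
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    if table == 1:
        codon_map, stops = _CODON_TO_AA, _STOP_CODONS
    else:
        t = CodonTable.unambiguous_dna_by_id[table]
        codon_map, stops = t.forward_table, frozenset(t.stop_codons)
    aa = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in stops:
            if i == len(nt) - 3:
                break
            aa.append("*")  # internal stop: caller's problem, keep explicit
        else:
            aa.append(codon_map.get(codon, "X"))
    return "".join(aa)


def _scan_frame(
    working: str, offset: int, min_aa: int, mode: str, include_incomplete: bool
) -> list[tuple[int, int]]:
    """ORF spans [start, end) on the working strand for one frame offset.

    ``end`` includes the stop codon. In ``maximal`` mode only the first ATG
    after the previous in-frame stop opens an ORF; in ``all-starts`` every
    ATG does.
    """
    spans: list[tuple[int, int]] = []
    open_starts: list[int] = []
    i = offset
    n = len(working)
    while i + 3 <= n:
        codon = working[i : i + 3]
        if codon in _STOP_CODONS:
            for s in open_starts:
                if (i - s) // 3 >= min_aa:
                    spans.append((s, i + 3))
            open_starts = []
        elif codon == _START_CODON and (mode == "all-starts" or not open_starts):
            open_starts.append(i)
        i += 3
    if include_incomplete:
        # Truncate at the last complete codon; no stop codon in the span.
        for s in open_starts:
            end = s + ((n - s) // 3) * 3
            if (end - s) // 3 >= min_aa:
                spans.append((s, end))
    return spans


def find_orfs(
    genome: GenomeSequence,
    min_aa: int = 50,
    mode: str = "maximal",
    include_incomplete: bool = False,
) -> list[OpenReadingFrame]:
    """Find ATG-initiated, stop-terminated ORFs in all six reading frames.

    Parameters
    ----------
    genome:
        Sequence to scan (degenerate IUPAC codes never match ATG or a stop).
    min_aa:
        Minimum translated length in amino acids; shorter ORFs are dropped.
    mode:
        ``"maximal"`` — only the first ATG after the previous in-frame stop
        opens an ORF; ``"all-starts"`` — every ATG opens one (so nested ORFs
        sharing a stop are all reported).
    include_incomplete:
        Also report ORFs truncated by the sequence end without a stop codon.

    Returns ORFs sorted by (strand, frame, start), '+' strand first.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if mode not in ("maximal", "all-starts"):
        raise ValueError(f"unknown mode {mode!r}")
    fwd = genome.seq.upper()
    rev = reverse_complement(fwd)
    n = len(fwd)
    orfs: list[OpenReadingFrame] = []
    for strand, working in (("+", fwd), ("-", rev)):
        for frame in range(3):
            for s, e in _scan_frame(working, frame, min_aa, mode, include_incomplete):
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = n - e, n - s
                orfs.append(
                    OpenReadingFrame(
                        genome_id=genome.id,
                        strand=strand,
                        frame=frame,
                        start=start,
                        end=end,
                        nt_seq=working[s:e],
                    )
                )
    orfs.sort(key=lambda o: (0 if o.strand == "+" else 1, o.frame, o.start))
    return orfs


def translate_orfs(orfs: Iterable[OpenReadingFrame]) -> list[ProteinSequence]:
    """Translate ORFs, excluding the stop codon from each protein."""
    return [ProteinSequence(orf_id=o.orf_id, aa_seq=translate(o.nt_seq)) for o in orfs]


def write_protein_fasta(proteins: Iterable[ProteinSequence], stream: TextIO) -> None:
    """Write proteins as FASTA, one record per protein, header = orf_id."""
    proteins = list(proteins)
    ids = [p.orf_id for p in proteins]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate orf_id(s): {dup}")
    records = [SeqRecord(Seq(p.aa_seq), id=p.orf_id, description="") for p in proteins]
    SeqIO.write(records, stream, "fasta")
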