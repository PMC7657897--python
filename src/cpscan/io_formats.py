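"""Reading and writing the formats the pipeline touches.

FASTA (nucleotide and protein), Clustal alignments, BED6 interval reports
and tab-separated tables. Parsing is delegated to Biopython; this module
adds strict alphabet validation and the normalisation rules the rest of
the pipeline relies on (upper-casing, U->T for DNA).

Coordinate convention: everything stored in domain objects is 1-based
inclusive (human-facing); BED output converts to 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

from Bio import AlignIO, SeqIO

DNA_LETTERS = frozenset("ACGTN")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX-")

Alphabet = Literal["dna", "protein"]


class FormatError(ValueError):
    """Raised on malformed input files or alphabet violations."""


@dataclass
class SeqRecord:
    """A named nucleotide or protein sequence.

    ``residues`` is upper case; DNA is over ``{A,C,G,T,N}`` (U normalised
    to T on construction via :func:`read_fasta`), protein over the 20
    amino-acid letters plus ``X`` and, in alignment rows, ``-``.
    """

    id: str
    residues: str
    alphabet: Alphabet = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be non-empty")
        if self.alphabet not in ("dna", "protein"):
            raise FormatError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length rows, at least one."""

    rows: list[SeqRecord]
    ncol: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment must contain at least one row")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise FormatError(f"unequal alignment lengths: {sorted(widths)}")
        self.ncol = widths.pop()

    def row(self, seq_id: str) -> SeqRecord:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(f"no alignment row with id {seq_id!r}")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]


def normalize_residues(raw: str, alphabet: Alphabet, *, record_id: str = "?") -> str:
    """Upper-case, apply U->T for DNA, and validate against the alphabet.

    Raises :class:`FormatError` naming the record and the 1-based offset
    of the first illegal character.
    """
    seq = raw.upper()
    if alphabet == "dna":
        seq = seq.replace("U", "T")
        allowed = DNA_LETTERS
    else:
        allowed = PROTEIN_LETTERS
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise FormatError(
                f"illegal {alphabet} character {ch!r} in record {record_id!r} at offset {i + 1}"
            )
    return seq


def read_fasta(path: Union[str, Path], alphabet: Alphabet) -> list[SeqRecord]:
    """Read a FASTA file into normalised :class:`SeqRecord` objects, in file order."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SeqRecord(
                id=rec.id,
                residues=normalize_residues(str(rec.seq), alphabet, record_id=rec.id),
                alphabet=alphabet,
                description=rec.description,
            )
        )
    if not records:
        raise FormatError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: Union[str, Path], width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: Union[str, Path], format: Literal["fasta", "clustal"] = "fasta",
                   alphabet: Alphabet = "protein") -> Msa:
    """Read a FASTA or Clustal alignment into an :class:`Msa` with equal-length rows."""
    try:
        if format == "clustal":
            aln = AlignIO.read(str(path), "clustal")
            raw = [(r.id, str(r.seq), r.description) for r in aln]
        elif format == "fasta":
            raw = [(r.id, str(r.seq), r.description) for r in SeqIO.parse(str(path), "fasta")]
        else:
            raise FormatError(f"unsupported alignment format {format!r}")
    except FormatError:
        raise
    except Exception as exc:  # Biopython raises bare ValueError on parse failure
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if not raw:
        raise FormatError(f"no records in {path}")
    rows = [
        SeqRecord(id=i, residues=normalize_residues(s, alphabet, record_id=i),
                  alphabet=alphabet, description=d)
        for i, s, d in raw
    ]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError("unequal alignment lengths")
    return Msa(rows=rows)


def write_clustal(msa: Msa, path: Union[str, Path]) -> None:
    """Write an alignment in Clustal format (via Biopython)."""
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord as BioRecord

    aln = MultipleSeqAlignment(
        [BioRecord(Seq(r.residues), id=r.id, description="") for r in msa.rows]
    )
    AlignIO.write(aln, str(path), "clustal")


def _bed_rows(hits: Sequence) -> list[tuple]:
    """Convert MotifHit / PairedMotif / Amplicon-like objects to BED6 tuples."""
    rows = []
    for h in hits:
        # PairedMotif spans first.start .. second.end; plain hits carry start/end
        if hasattr(h, "first") and hasattr(h, "second"):
            seq_id = h.first.seq_id
            start, end = h.first.start, h.second.end
            name = f"{h.first.pattern}|{h.second.pattern}|gap={h.gap}"
            score = h.first.mismatches + h.second.mismatches
            strand = h.first.strand
        else:
            seq_id = h.seq_id
            start, end = h.start, h.end
            name = h.pattern
            score = h.mismatches
            strand = h.strand
        rows.append((seq_id, start - 1, end, name, score, strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    return rows


def write_bed(hits: Sequence, path: Union[str, Path]) -> None:
    """Write hits or paired hits as BED6, 0-based half-open, sorted by chrom then start.

    The score column carries the mismatch count. An empty hit list produces
    a file holding only the header comment.
    """
    with open(path, "w") as fh:
        fh.write("# BED6: chrom\tstart\tend\tname\tscore(mismatches)\tstrand\n")
        for row in _bed_rows(hits):
            fh.write("\t".join(str(x) for x in row) + "\n")


def bed_lines(hits: Sequence) -> list[str]:
    """BED6 lines (no header) for in-memory use; same conventions as write_bed."""
    return ["\t".join(str(x) for x in row) for row in _bed_rows(hits)]
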