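"""Sequence containers, FASTA I/O, and genome fragmentation.

The pipeline works with plain nucleotide assemblies (sets of contigs) and
predicted proteomes. Coordinates are 0-based half-open everywhere inside the
package; 1-based numbering appears only in user-facing reports (signature
profile positions follow their own reference numbering, see
:mod:`stutzpan.signature`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# Full IUPAC sets: ambiguity codes are legal input (they occur in public 16S
# records) but never count as matches during alignment or signature checks.
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV-")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")
UNAMBIGUOUS_BASES = frozenset("ACGT")

Kind = Literal["nucleotide", "protein"]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (names the offending record)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence, nucleotide or protein, stored upper-case."""

    id: str
    sequence: str
    kind: Kind = "nucleotide"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence record with empty id")
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for {self.kind}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAssembly:
    """A named set of nucleotide contigs with optional provenance tag."""

    genome_id: str
    contigs: list[SequenceRecord]
    source_tag: str | None = None  # e.g. "isolate" vs "MAG"

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"assembly {self.genome_id!r} has no contigs")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"assembly {self.genome_id!r} has duplicate contig ids")
        if self.total_length == 0:
            raise ValueError(f"assembly {self.genome_id!r} has zero total length")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class Proteome:
    """Predicted protein set of one genome."""

    genome_id: str
    proteins: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.genome_id!r} is empty")
        ids = [p.id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError(f"proteome {self.genome_id!r} has duplicate protein ids")


@dataclass(frozen=True)
class Fragment:
    """A window cut from a contig; coordinates 0-based half-open."""

    parent_contig: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad fragment coordinates [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("fragment sequence length disagrees with coordinates")

    @property
    def fragment_id(self) -> str:
        return f"{self.parent_contig}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, kind: Kind = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into validated, upper-cased records.

    Raises :class:`FastaFormatError` on empty sequences, duplicate ids, or
    alphabet violations, naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), kind=kind, description=desc))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, sequence lines wrapped at ``width`` columns."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in FASTA output")
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def fragment_assembly(assembly: GenomeAssembly, fragment_length: int = 1020,
                      min_tail: int = 100) -> list[Fragment]:
    """Cut every contig into consecutive non-overlapping windows.

    Each contig is sliced left to right into ``fragment_length`` windows; a
    terminal remainder is kept if it is at least ``min_tail`` bases long and
    silently dropped otherwise. This is the canonical fragmentation used for
    fragment-based average nucleotide identity (ANIb).
    """
    if fragment_length < 100:
        raise ValueError("fragment_length must be >= 100")
    fragments: list[Fragment] = []
    for contig in assembly.contigs:
        seq = contig.sequence
        for start in range(0, len(seq), fragment_length):
            end = min(start + fragment_length, len(seq))
            if end - start < fragment_length and end - start < min_tail:
                break
            fragments.append(Fragment(contig.id, start, end, seq[start:end]))
    return fragments


def read_assembly(path: str | Path, genome_id: str | None = None,
                  source_tag: str | None = None) -> GenomeAssembly:
    """Read a nucleotide FASTA file as one :class:`GenomeAssembly`."""
    path = Path(path)
    return GenomeAssembly(genome_id or path.stem, read_fasta(path, "nucleotide"),
                          source_tag=source_tag)


def read_proteome(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read a protein FASTA file as one :class:`Proteome`."""
    path = Path(path)
    return Proteome(genome_id or path.stem, read_fasta(path, "protein"))


def read_strain_metadata(path: str | Path) -> pd.DataFrame:
    """Read the strain metadata TSV.

    Expected columns: ``strain_id``, ``label``, ``source_tags`` (semicolon
    separated, may be empty), ``geography``. ``source_tags`` is parsed into a
    python set per row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"strain_id", "label", "source_tags", "geography"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"strain metadata missing columns: {sorted(missing)}")
    if df["strain_id"].duplicated().any():
        dups = df.loc[df["strain_id"].duplicated(), "strain_id"].tolist()
        raise ValueError(f"duplicate strain ids: {dups}")
    df["source_tags"] = df["source_tags"].map(
        lambda s: {t.strip() for t in s.split(";") if t.strip()}
    )
    return df
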