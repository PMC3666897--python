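"""Sequence and alignment I/O, and reference-anchored position mapping.

All residue numbers and alignment columns are 1-based at the interface.
FASTA parsing is delegated to Biopython; a light pre-check produces
line-numbered errors for the malformations Bio.SeqIO tolerates silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import AlignmentShapeError, AnchorError, FastaParseError, RangeError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in unaligned sequence context
VALID_RESIDUES = AMINO_ACIDS | {"X"}
#: residues accepted in aligned context
VALID_ALIGNED = VALID_RESIDUES | {"-"}


def _normalize(residues: str, seq_id: str, aligned: bool) -> str:
    """Upper-case, map '.' to '-', and validate the alphabet."""
    s = residues.upper().replace(".", "-")
    allowed = VALID_ALIGNED if aligned else VALID_RESIDUES
    bad = set(s) - allowed
    if bad:
        raise FastaParseError(
            f"sequence {seq_id!r} contains invalid residue(s) {sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence, optionally carrying a species tag."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("record with empty id")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length gapped sequences."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment has no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            offenders = sorted(
                r.id for r in self.records
                if len(r.residues) != len(self.records[0].residues)
            )
            raise AlignmentShapeError(
                f"ragged alignment: records {offenders} differ in length"
            )
        all_gap = [r.id for r in self.records if not r.ungapped]
        if all_gap:
            raise AlignmentShapeError(f"all-gap record(s): {all_gap}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentShapeError("duplicate sequence ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise AnchorError(f"sequence id {seq_id!r} not in alignment")


@dataclass(frozen=True)
class PositionAnchor:
    """Mapping from 1-based reference residue numbers to alignment columns."""

    ref_id: str
    ref_positions: tuple[int, ...]
    columns: tuple[int, ...]


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, order preserved.

    The species tag is taken from the header token after the first
    whitespace, when present.
    """
    path = Path(path)
    _precheck_fasta(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = rec.description.split(None, 1)[1].strip() if " " in rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_normalize(str(rec.seq), rec.id, aligned=aligned),
                species=species,
            )
        )
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def _precheck_fasta(path: Path) -> None:
    """Raise a line-numbered error for input Bio.SeqIO would skip silently."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                )
            if len(line.strip()) == 1:
                raise FastaParseError(f"{path}: line {lineno}: empty FASTA header")
            return
    raise FastaParseError(f"{path}: empty file")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id} {r.species}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; validates equal lengths and no all-gap rows."""
    return Alignment(records=tuple(read_fasta(path, aligned=True)))


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column tab-delimited file: sequence id, species tag."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FastaParseError(
                    f"{path}: line {lineno}: expected two tab-separated columns"
                )
            mapping[parts[0]] = parts[1]
    return mapping


def anchor_positions(
    alignment: Alignment, ref_id: str, ref_positions: Iterable[int]
) -> PositionAnchor:
    """Locate alignment columns holding given reference residue numbers.

    Columns are found by counting non-gap characters in the reference row;
    both residue numbers and columns are 1-based.
    """
    ref = alignment.record(ref_id)
    positions = tuple(int(p) for p in ref_positions)
    ungapped_len = len(ref.ungapped)
    # residue number -> column, built in one pass over the reference row
    pos_to_col: dict[int, int] = {}
    n = 0
    for col, ch in enumerate(ref.residues, start=1):
        if ch != "-":
            n += 1
            pos_to_col[n] = col
    columns = []
    for p in positions:
        if p < 1 or p > ungapped_len:
            raise AnchorError(
                f"residue number {p} outside reference {ref_id!r} (length {ungapped_len})"
            )
        columns.append(pos_to_col[p])
    return PositionAnchor(ref_id=ref_id, ref_positions=positions, columns=tuple(columns))


def column_residues(alignment: Alignment, column: int) -> dict[str, str]:
    """Residue (or '-') of every record at a 1-based alignment column."""
    if column < 1 or column > alignment.length:
        raise RangeError(f"column {column} outside alignment of length {alignment.length}")
    return {r.id: r.residues[column - 1] for r in alignment.records}
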