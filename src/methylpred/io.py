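"""Readers and writers for every external artifact.

Formats handled here: FASTA protein sequences, tab-separated site
annotations (``protein_id  position  residue  label``), per-residue
solvent-accessible surface area (ASA) tracks
(``protein_id  position  asa_percent``), and the residue property table
(physicochemical group plus normalized van der Waals volume).

All TSV dialects are UTF-8, require a header line, and ignore lines
starting with ``#``.  Positions are 1-based in files and converted to
0-based offsets internally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes tolerated in sequences; encoders treat them like pads.
AMBIGUOUS_RESIDUES = "BJOUXZ"
ALLOWED_RESIDUES = set(STANDARD_RESIDUES + AMBIGUOUS_RESIDUES)

#: Physicochemical grouping: hydrophobic / polar / positively charged /
#: negatively charged.
GROUP_DEFINITIONS = {
    1: frozenset("AFGILMPVW"),
    2: frozenset("CNQSTY"),
    3: frozenset("HKR"),
    4: frozenset("DE"),
}


class FormatError(ValueError):
    """A file violates its declared dialect or an invariant."""


@dataclass
class ProteinRecord:
    """A named amino-acid sequence with an optional per-residue ASA track."""

    id: str
    sequence: str
    asa: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid protein id {self.id!r}")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.id!r} contains invalid residue(s) {sorted(bad)}"
            )
        if self.asa is not None and len(self.asa) != len(self.sequence):
            raise FormatError(
                f"protein {self.id!r}: ASA track length {len(self.asa)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteInstance:
    """One candidate methylation site (1-based position, residue R or K)."""

    protein_id: str
    position: int
    residue: str
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.residue not in ("R", "K"):
            raise FormatError(
                f"site {self.protein_id}:{self.position}: residue must be "
                f"R or K, got {self.residue!r}"
            )
        if self.label not in ("positive", "negative"):
            raise FormatError(
                f"site {self.protein_id}:{self.position}: label must be "
                f"positive or negative, got {self.label!r}"
            )


@dataclass(frozen=True)
class PropertyTable:
    """Residue → physicochemical group (1..4) and normalized VDWV maps."""

    group_of: dict[str, int] = field(repr=False)
    vdwv_of: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        residues = set(self.group_of)
        if residues != set(STANDARD_RESIDUES):
            missing = set(STANDARD_RESIDUES) - residues
            extra = residues - set(STANDARD_RESIDUES)
            raise FormatError(
                f"property table must cover exactly the 20 standard residues "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        if set(self.vdwv_of) != set(STANDARD_RESIDUES):
            raise FormatError("VDWV values must cover all 20 standard residues")
        if set(self.group_of.values()) - {1, 2, 3, 4}:
            raise FormatError("group indices must lie in 1..4")
        # The four groups are fixed by the coding scheme's definition.
        for residue, group in self.group_of.items():
            if residue not in GROUP_DEFINITIONS[group]:
                raise FormatError(
                    f"residue {residue!r} assigned to group {group}, which "
                    f"violates the canonical hydrophobic/polar/charged partition"
                )

    def vdwv_range(self) -> tuple[float, float]:
        return min(self.vdwv_of.values()), max(self.vdwv_of.values())


def _data_rows(path: Path, n_cols: int) -> Iterable[list[str]]:
    """Yield non-comment rows of a TSV after validating the header."""
    with open(path, encoding="utf-8") as handle:
        reader = csv.reader(
            (line for line in handle if not line.startswith("#")),
            delimiter="\t",
        )
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header required") from None
        if len(header) < n_cols:
            raise FormatError(f"{path}: header has fewer than {n_cols} columns")
        for row in reader:
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < n_cols:
                raise FormatError(f"{path}: short row {row!r}")
            yield row


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load protein records from a FASTA file.

    Sequences are upper-cased; duplicate identifiers are rejected.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FormatError(f"{path}: FASTA entry with empty id")
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate protein id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                handle.write(rec.sequence[i : i + 60] + "\n")


def read_sites(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[SiteInstance]:
    """Load site annotations and validate each against its protein.

    Every row must name a known protein, an in-range 1-based position,
    and a residue matching the protein sequence at that position.  Rows
    are never silently dropped.
    """
    path = Path(path)
    by_id = {p.id: p for p in proteins}
    sites = []
    for row in _data_rows(path, 4):
        pid, pos_s, residue, label = row[0], row[1], row[2], row[3]
        if pid not in by_id:
            raise FormatError(f"{path}: unknown protein id {pid!r}")
        protein = by_id[pid]
        try:
            position = int(pos_s)
        except ValueError:
            raise FormatError(f"{path}: non-integer position {pos_s!r}") from None
        if not 1 <= position <= len(protein):
            raise FormatError(
                f"{path}: position {position} out of range for protein "
                f"{pid!r} of length {len(protein)}"
            )
        actual = protein.sequence[position - 1]
        if actual != residue:
            raise FormatError(
                f"{path}: protein {pid!r} position {position} is {actual!r}, "
                f"annotation says {residue!r}"
            )
        sites.append(
            SiteInstance(pid, position, residue, label, source=str(path))
        )
    return sites


def write_sites(sites: Sequence[SiteInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("protein_id\tposition\tresidue\tlabel\n")
        for s in sites:
            handle.write(f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.label}\n")


def read_asa(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Attach per-residue ASA tracks (percent, 0–100) to proteins.

    A track must be complete for every protein it mentions; proteins
    absent from the file keep ``asa=None``.  Returns new records.
    """
    path = Path(path)
    by_id = {p.id: p for p in proteins}
    values: dict[str, dict[int, float]] = {}
    for row in _data_rows(path, 3):
        pid, pos_s, asa_s = row[0], row[1], row[2]
        if pid not in by_id:
            raise FormatError(f"{path}: unknown protein id {pid!r}")
        position = int(pos_s)
        asa = float(asa_s)
        if not 0.0 <= asa <= 100.0:
            raise FormatError(
                f"{path}: ASA {asa} outside [0, 100] at {pid}:{position}"
            )
        if not 1 <= position <= len(by_id[pid]):
            raise FormatError(f"{path}: position {position} out of range for {pid}")
        track = values.setdefault(pid, {})
        if position in track:
            raise FormatError(f"{path}: duplicate ASA row for {pid}:{position}")
        track[position] = asa

    out = []
    for protein in proteins:
        track = values.get(protein.id)
        if track is None:
            out.append(protein)
            continue
        missing = [i for i in range(1, len(protein) + 1) if i not in track]
        if missing:
            raise FormatError(
                f"{path}: incomplete ASA track for {protein.id!r} "
                f"(first missing position {missing[0]})"
            )
        out.append(
            replace(protein, asa=[track[i] for i in range(1, len(protein) + 1)])
        )
    return out


def write_asa(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("protein_id\tposition\tasa_percent\n")
        for p in proteins:
            if p.asa is None:
                continue
            for i, value in enumerate(p.asa, start=1):
                handle.write(f"{p.id}\t{i}\t{value:.2f}\n")


def read_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load a residue property table; the packaged default when path is None.

    The default table carries the canonical four-group partition
    (hydrophobic / polar / positively charged / negatively charged) and
    unit-interval normalized van der Waals volumes.
    """
    if path is None:
        ref = resources.files("methylpred.data") / "vdwv_groups.tsv"
        with resources.as_file(ref) as p:
            return _parse_property_table(Path(p))
    return _parse_property_table(Path(path))


def _parse_property_table(path: Path) -> PropertyTable:
    group_of: dict[str, int] = {}
    vdwv_of: dict[str, float] = {}
    for row in _data_rows(path, 3):
        residue, group_s, vdwv_s = row[0], row[1], row[2]
        if residue in group_of:
            raise FormatError(
                f"{path}: residue {residue!r} listed in more than one group"
            )
        group_of[residue] = int(group_s)
        vdwv_of[residue] = float(vdwv_s)
    return PropertyTable(group_of=group_of, vdwv_of=vdwv_of)
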