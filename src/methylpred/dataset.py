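"""Peptide dataset construction.

Candidate methylation sites (arginine or lysine) are cut from their
proteins as fixed-length windows of ``2L+1`` residues with the candidate
at the center; positions beyond the protein termini are padded with
``'X'`` (ASA pad value 0).  Annotated sites become positives; every
other residue of the same type in annotated proteins becomes a
negative.  Duplicate peptides are reduced, and negative training sets
are drawn at a chosen positive:negative ratio with replicated draws so
downstream performance can be averaged over replicates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import ProteinRecord, SiteInstance

PAD = "X"
DEFAULT_L = 7  # default window size 15


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideWindow:
    """A ``2L+1``-mer centered on a candidate R/K site.

    ``asa`` is the aligned percent-exposure track (pads contribute 0) or
    ``None`` when the source protein carried no ASA data.
    """

    sequence: str
    label: str
    protein_id: str
    position: int  # 1-based center position in the source protein
    asa: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 != 1:
            raise DatasetError(f"window length {len(self.sequence)} is not odd")
        if self.center_residue not in ("R", "K"):
            raise DatasetError(
                f"window center must be R or K, got {self.center_residue!r} "
                f"({self.protein_id}:{self.position})"
            )
        if self.asa is not None and len(self.asa) != len(self.sequence):
            raise DatasetError("ASA track length differs from window length")
        if self.label not in ("positive", "negative"):
            raise DatasetError(f"bad label {self.label!r}")

    @property
    def L(self) -> int:
        return len(self.sequence) // 2

    @property
    def center_residue(self) -> str:
        return self.sequence[len(self.sequence) // 2]


@dataclass
class DatasetBundle:
    """Positives plus replicated negative draws at a fixed ratio."""

    positives: list[PeptideWindow]
    negative_sets: list[list[PeptideWindow]]
    ratio: int
    seed: int

    @property
    def protein_ids(self) -> set[str]:
        ids = {w.protein_id for w in self.positives}
        for ns in self.negative_sets:
            ids |= {w.protein_id for w in ns}
        return ids


def extract_window(
    protein: ProteinRecord,
    position: int,
    L: int,
    label: str = "negative",
) -> PeptideWindow:
    """Cut the symmetric ``2L+1`` window centered at a 1-based position."""
    if L < 1:
        raise DatasetError(f"L must be >= 1, got {L}")
    if not 1 <= position <= len(protein):
        raise DatasetError(
            f"position {position} out of range for {protein.id!r}"
        )
    center = protein.sequence[position - 1]
    if center not in ("R", "K"):
        raise DatasetError(
            f"{protein.id}:{position} is {center!r}, not a methylatable R/K"
        )
    seq_chars = []
    asa_vals: Optional[list[float]] = [] if protein.asa is not None else None
    for offset in range(-L, L + 1):
        idx = position - 1 + offset
        if 0 <= idx < len(protein):
            seq_chars.append(protein.sequence[idx])
            if asa_vals is not None:
                asa_vals.append(protein.asa[idx])
        else:
            seq_chars.append(PAD)
            if asa_vals is not None:
                asa_vals.append(0.0)
    return PeptideWindow(
        sequence="".join(seq_chars),
        label=label,
        protein_id=protein.id,
        position=position,
        asa=tuple(asa_vals) if asa_vals is not None else None,
    )


def enumerate_candidates(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteInstance],
    residue_type: str,
    L: int = DEFAULT_L,
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """All candidate windows of one residue type, split by label.

    Positives are the annotated sites; negatives are every other
    occurrence of the residue type in proteins carrying at least one
    annotation (unannotated sites are presumed unmethylated).
    """
    if residue_type not in ("R", "K"):
        raise DatasetError(f"residue_type must be 'R' or 'K', got {residue_type!r}")
    by_id = {p.id: p for p in proteins}
    positive_keys: set[tuple[str, int]] = set()
    annotated_proteins: set[str] = set()
    for site in sites:
        if site.protein_id not in by_id:
            raise DatasetError(f"site references unknown protein {site.protein_id!r}")
        annotated_proteins.add(site.protein_id)
        if site.residue == residue_type and site.label == "positive":
            positive_keys.add((site.protein_id, site.position))

    positives: list[PeptideWindow] = []
    negatives: list[PeptideWindow] = []
    for protein in proteins:
        if protein.id not in annotated_proteins:
            continue
        for idx, residue in enumerate(protein.sequence):
            if residue != residue_type:
                continue
            position = idx + 1
            if (protein.id, position) in positive_keys:
                positives.append(extract_window(protein, position, L, "positive"))
            else:
                negatives.append(extract_window(protein, position, L, "negative"))
    return positives, negatives


def deduplicate(windows: Sequence[PeptideWindow]) -> list[PeptideWindow]:
    """Reduce redundant peptides.

    Among windows with identical sequence and label only the first in
    input order is kept; a negative whose peptide also occurs as a
    positive is removed (the positive annotation is the trusted one).
    """
    positive_seqs = {w.sequence for w in windows if w.label == "positive"}
    seen: set[tuple[str, str]] = set()
    kept = []
    for w in windows:
        if w.label == "negative" and w.sequence in positive_seqs:
            continue
        key = (w.sequence, w.label)
        if key in seen:
            continue
        seen.add(key)
        kept.append(w)
    return kept


def sample_negative_sets(
    negatives: Sequence[PeptideWindow],
    n_positives: int,
    ratio: int,
    n_sets: int,
    seed: int,
) -> list[list[PeptideWindow]]:
    """Draw ``n_sets`` replicate negative sets of size ratio·n_positives.

    Draws are uniform without replacement within a set, independent
    across sets, and fully reproducible from the seed.  The set size is
    capped at the number of available negatives.
    """
    if not negatives:
        raise DatasetError("no negative windows to sample from")
    if ratio < 1:
        raise DatasetError(f"ratio must be >= 1, got {ratio}")
    if n_sets < 1:
        raise DatasetError(f"n_sets must be >= 1, got {n_sets}")
    size = min(ratio * n_positives, len(negatives))
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        idx = rng.choice(len(negatives), size=size, replace=False)
        sets.append([negatives[i] for i in idx])
    return sets


def build_bundle(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteInstance],
    residue_type: str,
    L: int = DEFAULT_L,
    ratio: int = 1,
    n_sets: int = 5,
    seed: int = 0,
) -> DatasetBundle:
    """Full dataset construction: enumerate, deduplicate, sample replicates."""
    positives, negatives = enumerate_candidates(proteins, sites, residue_type, L)
    reduced = deduplicate(positives + negatives)
    positives = [w for w in reduced if w.label == "positive"]
    negatives = [w for w in reduced if w.label == "negative"]
    if not positives:
        raise DatasetError("no positive sites for the requested residue type")
    negative_sets = sample_negative_sets(
        negatives, len(positives), ratio, n_sets, seed
    )
    return DatasetBundle(positives, negative_sets, ratio=ratio, seed=seed)


def dedup_proteins(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop proteins whose full sequence exactly duplicates an earlier one.

    Homology reduction below exact identity (e.g. 40% clustering) is an
    upstream responsibility.
    """
    seen: set[str] = set()
    kept = []
    for p in proteins:
        if p.sequence in seen:
            continue
        seen.add(p.sequence)
        kept.append(p)
    return kept


def write_windows(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    """Persist windows as TSV: sequence, label, protein_id, position, asa_csv."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("sequence\tlabel\tprotein_id\tposition\tasa_csv\n")
        for w in windows:
            asa_csv = (
                ",".join(f"{v:.2f}" for v in w.asa) if w.asa is not None else ""
            )
            handle.write(
                f"{w.sequence}\t{w.label}\t{w.protein_id}\t{w.position}\t{asa_csv}\n"
            )


def read_windows(path: str | Path) -> list[PeptideWindow]:
    windows = []
    with open(path, encoding="utf-8") as handle:
        reader = csv.reader(
            (line for line in handle if not line.startswith("#")), delimiter="\t"
        )
        header = next(reader)
        if header[0] != "sequence":
            raise DatasetError(f"{path}: unexpected header {header!r}")
        for row in reader:
            if not row:
                continue
            seq, label, pid, pos, asa_csv = row[:5]
            asa = (
                tuple(float(v) for v in asa_csv.split(",")) if asa_csv else None
            )
            windows.append(PeptideWindow(seq, label, pid, int(pos), asa))
    return windows
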