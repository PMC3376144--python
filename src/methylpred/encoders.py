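"""The enhanced feature encoding scheme.

A peptide window of ``N = 2L+1`` residues is mapped to the concatenation
of up to four feature blocks, in canonical order:

SPC (sparse property coding), ``4N`` components
    Each residue contributes a 4-slot one-hot (Kronecker delta) of its
    physicochemical group: hydrophobic {A,F,G,I,L,M,P,V,W}, polar
    {C,N,Q,S,T,Y}, positively charged {H,K,R}, negatively charged {D,E}.
    Methylation increases side-chain hydrophobicity without changing
    charge, which is why this grouping is informative.

VDWV (normalized van der Waals volume), ``N`` components
    The tabulated unit-interval side-chain volume of each residue.

PWAA (position-weight amino-acid composition), 20 components
    For amino acid :math:`a_i`,

    .. math:: C_i = \\frac{1}{L(L+1)} \\sum_{j=-L}^{L}
              x_{i,j}\\,\\Bigl(j + \\frac{|j|}{L}\\Bigr)

    where :math:`x_{i,j}=1` iff :math:`a_i` occupies offset ``j``.  The
    weight's absolute value, :math:`|j|(L+1)/L \\cdot (L(L+1))^{-1} =
    |j|/L^2`, grows with distance from the central site, so the encoding
    preserves sequence-order information: occurrences far from the
    center move the component further from zero, with opposite signs
    up- and downstream.

ASA (solvent-accessible surface area), ``N`` components
    Per-residue percent exposure divided by 100.

Terminal pads ('X') and ambiguity codes contribute all-zero slots in
every block, so vector length is fixed by ``L`` and the enabled blocks
alone.  With all four blocks at the default window of 15 the vector has
60 + 15 + 20 + 15 = 110 components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import PeptideWindow
from .io import STANDARD_RESIDUES, PropertyTable, read_property_table

logger = logging.getLogger(__name__)

#: Canonical block order; config order never changes the layout.
BLOCK_ORDER = ("SPC", "VDWV", "PWAA", "ASA")

#: Fixed amino-acid ordering for the PWAA block.
AA_ORDER = STANDARD_RESIDUES


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    """Which feature blocks are enabled, for what flank length L."""

    enabled_blocks: tuple[str, ...] = BLOCK_ORDER
    L: int = 7
    property_table: PropertyTable = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        blocks = tuple(b for b in BLOCK_ORDER if b in self.enabled_blocks)
        unknown = set(self.enabled_blocks) - set(BLOCK_ORDER)
        if unknown:
            raise EncodingError(f"unknown feature block(s) {sorted(unknown)}")
        if not blocks:
            raise EncodingError("at least one feature block must be enabled")
        object.__setattr__(self, "enabled_blocks", blocks)
        if self.L < 1:
            raise EncodingError(f"L must be >= 1, got {self.L}")
        if self.property_table is None:
            object.__setattr__(self, "property_table", read_property_table())

    @property
    def window_size(self) -> int:
        return 2 * self.L + 1

    def block_length(self, block: str) -> int:
        n = self.window_size
        return {"SPC": 4 * n, "VDWV": n, "PWAA": 20, "ASA": n}[block]

    def layout(self) -> dict[str, tuple[int, int]]:
        """Half-open index range of each enabled block, tiling the vector."""
        out: dict[str, tuple[int, int]] = {}
        start = 0
        for block in self.enabled_blocks:
            end = start + self.block_length(block)
            out[block] = (start, end)
            start = end
        return out

    @property
    def n_features(self) -> int:
        return sum(self.block_length(b) for b in self.enabled_blocks)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    layout: dict[str, tuple[int, int]]

    def block(self, name: str) -> np.ndarray:
        start, end = self.layout[name]
        return self.values[start:end]


def _check_window(window: PeptideWindow, L: int) -> None:
    if window.L != L:
        raise EncodingError(
            f"window has L={window.L}, encoder configured for L={L}"
        )


def spc_encode(window: PeptideWindow, table: PropertyTable) -> np.ndarray:
    """Sparse property coding: 4 one-hot group slots per residue (4N)."""
    n = len(window.sequence)
    out = np.zeros(4 * n)
    for k, residue in enumerate(window.sequence):
        group = table.group_of.get(residue)
        if group is not None:
            out[4 * k + group - 1] = 1.0
    return out


def vdwv_encode(window: PeptideWindow, table: PropertyTable) -> np.ndarray:
    """Normalized van der Waals volume of each residue (N); pads are 0."""
    return np.array(
        [table.vdwv_of.get(residue, 0.0) for residue in window.sequence]
    )


def pwaa_weight(j: int, L: int) -> float:
    """Position weight of offset j in a window with flank length L."""
    return (j + abs(j) / L) / (L * (L + 1))


def pwaa_encode(window: PeptideWindow) -> np.ndarray:
    """Position-weight amino-acid composition (20 components).

    Component i sums the position weights of every occurrence of amino
    acid i across offsets -L..L; pads and ambiguity codes contribute
    nothing.
    """
    L = window.L
    out = np.zeros(20)
    index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for k, residue in enumerate(window.sequence):
        i = index.get(residue)
        if i is not None:
            j = k - L
            out[i] += j + abs(j) / L
    return out / (L * (L + 1))


def asa_encode(window: PeptideWindow) -> np.ndarray:
    """Solvent-accessible surface area, percent/100 per residue (N).

    A window from a protein without an ASA track encodes as all zeros
    (logged once per call site pattern rather than raising: absence of
    structural data should degrade, not abort, a prediction).
    """
    if window.asa is None:
        logger.warning(
            "window %s:%d has no ASA track; ASA block encoded as zeros",
            window.protein_id,
            window.position,
        )
        return np.zeros(len(window.sequence))
    return np.asarray(window.asa) / 100.0


_BLOCK_ENCODERS = {
    "SPC": lambda w, cfg: spc_encode(w, cfg.property_table),
    "VDWV": lambda w, cfg: vdwv_encode(w, cfg.property_table),
    "PWAA": lambda w, cfg: pwaa_encode(w),
    "ASA": lambda w, cfg: asa_encode(w),
}


def encode(window: PeptideWindow, config: EncoderConfig) -> FeatureVector:
    """Concatenate the enabled blocks in canonical order."""
    _check_window(window, config.L)
    parts = [_BLOCK_ENCODERS[b](window, config) for b in config.enabled_blocks]
    return FeatureVector(values=np.concatenate(parts), layout=config.layout())


def encode_windows(
    windows: Sequence[PeptideWindow], config: EncoderConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Encode many windows into a feature matrix and 0/1 label vector."""
    if not windows:
        return (
            np.empty((0, config.n_features)),
            np.empty(0, dtype=int),
        )
    X = np.vstack([encode(w, config).values for w in windows])
    y = np.array([1 if w.label == "positive" else 0 for w in windows])
    return X, y


def write_feature_matrix(
    windows: Sequence[PeptideWindow],
    config: EncoderConfig,
    path,
) -> None:
    """TSV feature matrix: one column per component named BLOCK[i], label last."""
    X, y = encode_windows(windows, config)
    names: list[str] = []
    for block in config.enabled_blocks:
        names.extend(f"{block}[{i}]" for i in range(config.block_length(block)))
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(names + ["label"]) + "\n")
        for row, label in zip(X, y):
            handle.write(
                "\t".join(f"{v:.6g}" for v in row)
                + f"\t{'positive' if label else 'negative'}\n"
            )


def read_feature_matrix(path) -> tuple[np.ndarray, np.ndarray, dict[str, tuple[int, int]]]:
    """Load a TSV feature matrix; returns (X, y, layout)."""
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[-1] != "label":
            raise EncodingError(f"{path}: last column must be 'label'")
        layout: dict[str, tuple[int, int]] = {}
        for idx, name in enumerate(header[:-1]):
            block = name.split("[", 1)[0]
            if block not in layout:
                layout[block] = (idx, idx)
            layout[block] = (layout[block][0], idx + 1)
        rows, labels = [], []
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[:-1]])
            labels.append(1 if parts[-1] == "positive" else 0)
    return np.asarray(rows), np.asarray(labels, dtype=int), layout
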