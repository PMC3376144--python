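"""Positional feature analyses around candidate methylation sites.

Given aligned peptide windows, these routines compute, per offset from
the central residue: the fraction of residues in each physicochemical
group, the mean (±sd) of a numeric residue property (van der Waals
volume or solvent exposure), and the 20-row amino-acid frequency matrix
that underlies sequence logos.  Class differences at an offset are
assessed with Welch's unequal-variance t-test.

Pads ('X') and ambiguity codes are excluded from every denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PeptideWindow
from .encoders import AA_ORDER
from .io import PropertyTable


class AnalysisError(ValueError):
    pass


@dataclass
class PositionProfile:
    """A per-offset statistic for one class of windows."""

    name: str
    offsets: np.ndarray
    values: np.ndarray  # fraction or mean, NaN where n == 0
    sd: Optional[np.ndarray]
    n: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        data = {"offset": self.offsets, "value": self.values, "n": self.n}
        if self.sd is not None:
            data["sd"] = self.sd
        return pd.DataFrame(data)


@dataclass(frozen=True)
class TestResult:
    """Welch's t-test outcome at one window offset."""

    statistic: float
    df: float
    p_value: float
    offset: Optional[int] = None
    degenerate: bool = False


def _common_L(windows: Sequence[PeptideWindow]) -> int:
    if not windows:
        raise AnalysisError("no windows to analyze")
    L = windows[0].L
    if any(w.L != L for w in windows):
        raise AnalysisError("windows have mixed lengths")
    return L


def group_fraction_profile(
    windows: Sequence[PeptideWindow],
    table: PropertyTable,
    label: str = "",
) -> dict[int, PositionProfile]:
    """Fraction of residues in each group (1..4) at each offset.

    At every offset the four fractions sum to 1 over the non-pad
    residues; an offset with only pads gets NaN fractions and n = 0.
    """
    L = _common_L(windows)
    offsets = np.arange(-L, L + 1)
    counts = np.zeros((4, 2 * L + 1))
    totals = np.zeros(2 * L + 1)
    for w in windows:
        for k, residue in enumerate(w.sequence):
            group = table.group_of.get(residue)
            if group is not None:
                counts[group - 1, k] += 1
                totals[k] += 1
    with np.errstate(invalid="ignore"):
        fractions = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    return {
        g: PositionProfile(
            name=f"G{g}_fraction",
            offsets=offsets,
            values=fractions[g - 1],
            sd=None,
            n=totals.astype(int),
            label=label,
        )
        for g in (1, 2, 3, 4)
    }


def numeric_profile(
    windows: Sequence[PeptideWindow],
    prop: str,
    table: Optional[PropertyTable] = None,
    label: str = "",
) -> PositionProfile:
    """Per-offset mean ± sd of a numeric residue property.

    ``prop`` is ``"VDWV"`` (requires ``table``) or ``"ASA"`` (percent
    values; windows without ASA tracks are skipped).
    """
    L = _common_L(windows)
    offsets = np.arange(-L, L + 1)
    samples: list[list[float]] = [[] for _ in range(2 * L + 1)]
    if prop == "VDWV":
        if table is None:
            raise AnalysisError("VDWV profile requires a property table")
        for w in windows:
            for k, residue in enumerate(w.sequence):
                value = table.vdwv_of.get(residue)
                if value is not None:
                    samples[k].append(value)
    elif prop == "ASA":
        for w in windows:
            if w.asa is None:
                continue
            for k, residue in enumerate(w.sequence):
                if residue != "X":
                    samples[k].append(w.asa[k])
    else:
        raise AnalysisError(f"unknown property {prop!r}")
    n = np.array([len(s) for s in samples])
    values = np.array([np.mean(s) if s else np.nan for s in samples])
    sd = np.array([np.std(s, ddof=1) if len(s) > 1 else 0.0 for s in samples])
    return PositionProfile(
        name=f"{prop}_mean", offsets=offsets, values=values, sd=sd, n=n, label=label
    )


def positionwise_welch(
    values_pos: Sequence[float],
    values_neg: Sequence[float],
    offset: Optional[int] = None,
) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    t = (m1 - m2) / sqrt(s1²/n1 + s2²/n2), with Welch–Satterthwaite
    degrees of freedom.  Degenerate inputs (a sample smaller than 2, or
    zero variance on both sides with unequal means) are flagged rather
    than raised.
    """
    a = np.asarray(values_pos, dtype=float)
    b = np.asarray(values_neg, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return TestResult(math.nan, math.nan, math.nan, offset, degenerate=True)
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    n1, n2 = len(a), len(b)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if np.mean(a) == np.mean(b):
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, offset)
        return TestResult(math.inf, math.nan, 0.0, offset, degenerate=True)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(se2)
    df = se2**2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, offset)


def group_enrichment_test(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    table: PropertyTable,
    group: int,
    offset: int,
) -> TestResult:
    """Welch test of group membership (0/1 per window) at one offset.

    Each window contributes a binary indicator of whether its residue at
    the offset belongs to the group; pad positions are excluded.
    """
    L = _common_L(list(positives) + list(negatives))
    if not -L <= offset <= L:
        raise AnalysisError(f"offset {offset} outside window ±{L}")
    k = offset + L

    def indicators(windows: Sequence[PeptideWindow]) -> list[float]:
        out = []
        for w in windows:
            g = table.group_of.get(w.sequence[k])
            if g is not None:
                out.append(1.0 if g == group else 0.0)
        return out

    return positionwise_welch(indicators(positives), indicators(negatives), offset)


def residue_enrichment_test(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    residue: str,
    offset: int,
) -> TestResult:
    """Welch test of a single residue's occurrence at one offset."""
    L = _common_L(list(positives) + list(negatives))
    k = offset + L

    def indicators(windows: Sequence[PeptideWindow]) -> list[float]:
        return [
            1.0 if w.sequence[k] == residue else 0.0
            for w in windows
            if w.sequence[k] in AA_ORDER
        ]

    return positionwise_welch(indicators(positives), indicators(negatives), offset)


def numeric_property_tests(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    prop: str,
    table: Optional[PropertyTable] = None,
) -> list[TestResult]:
    """Welch tests of a numeric property at every offset."""
    L = _common_L(list(positives) + list(negatives))
    results = []
    for offset in range(-L, L + 1):
        k = offset + L
        pos_vals, neg_vals = [], []
        for windows, acc in ((positives, pos_vals), (negatives, neg_vals)):
            for w in windows:
                if prop == "VDWV":
                    value = table.vdwv_of.get(w.sequence[k]) if table else None
                    if value is not None:
                        acc.append(value)
                elif prop == "ASA":
                    if w.asa is not None and w.sequence[k] != "X":
                        acc.append(w.asa[k])
                else:
                    raise AnalysisError(f"unknown property {prop!r}")
        results.append(positionwise_welch(pos_vals, neg_vals, offset))
    return results


def frequency_matrix(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    """Column-normalized 20×(2L+1) amino-acid frequency matrix.

    Rows are the 20 standard residues, columns the offsets −L..L; each
    column sums to 1 over the non-pad residues observed there (NaN for
    all-pad columns).  This is the matrix a sequence-logo renderer
    consumes.
    """
    L = _common_L(windows)
    offsets = list(range(-L, L + 1))
    counts = np.zeros((20, 2 * L + 1))
    index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for w in windows:
        for k, residue in enumerate(w.sequence):
            i = index.get(residue)
            if i is not None:
                counts[i, k] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    return pd.DataFrame(freqs, index=list(AA_ORDER), columns=offsets)


def write_pwm(matrix: pd.DataFrame, path) -> None:
    """Write a frequency matrix in a plain position-weight-matrix layout."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("PO\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        for residue, row in matrix.iterrows():
            handle.write(
                residue + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n"
            )
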