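"""From-the-definition brute-force encoders and metric formulas.

These are deliberately independent re-implementations used only as test
oracles; they share no code with the package's encoders.
"""

import math

HYDROPHOBIC = set("AFGILMPVW")
POLAR = set("CNQSTY")
POSITIVE = set("HKR")
NEGATIVE = set("DE")
GROUPS = [HYDROPHOBIC, POLAR, POSITIVE, NEGATIVE]

AA = "ACDEFGHIKLMNPQRSTVWY"


def spc_oracle(sequence: str) -> list[float]:
    out = []
    for residue in sequence:
        for group in GROUPS:
            out.append(1.0 if residue in group else 0.0)
    return out


def vdwv_oracle(sequence: str, vdwv: dict) -> list[float]:
    return [vdwv[r] if r in vdwv else 0.0 for r in sequence]


def pwaa_oracle(sequence: str) -> list[float]:
    # C_i = (1/(L(L+1))) * sum_j x_ij * (j + |j|/L), j = -L..L
    n = len(sequence)
    L = n // 2
    out = []
    for aa in AA:
        total = 0.0
        for j in range(-L, L + 1):
            if sequence[j + L] == aa:
                total += j + abs(j) / L
        out.append(total / (L * (L + 1)))
    return out


def asa_oracle(asa_track, n: int) -> list[float]:
    if asa_track is None:
        return [0.0] * n
    return [v / 100.0 for v in asa_track]


def metrics_oracle(tp: int, fp: int, tn: int, fn: int):
    """Direct evaluation of the Sn/Sp/Acc/MCC definitions."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + fp + tn + fn)
    root = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(root) if root else 0.0
    return sn, sp, acc, mcc
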