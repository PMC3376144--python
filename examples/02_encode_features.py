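"""Encode one peptide window with the four-block feature scheme.

Prints each block of the 110-dimensional vector for a hand-built
15-mer so the layout is visible: sparse property coding (60), van der
Waals volume (15), position-weight amino-acid composition (20), and
solvent exposure (15).
"""

import numpy as np

from methylpred import EncoderConfig, encode
from methylpred.dataset import PeptideWindow

window = PeptideWindow(
    sequence="XXAGFGGRGGFKLMS",  # glycine-rich arginine context
    label="positive",
    protein_id="demo",
    position=8,
    asa=(0.0, 0.0, 42.0, 55.0, 38.0, 61.0, 70.0, 66.0, 58.0, 49.0, 52.0,
         44.0, 35.0, 28.0, 31.0),
)

config = EncoderConfig()  # all four blocks, window 15
fv = encode(window, config)
print(f"vector length: {len(fv.values)}")
for block, (start, end) in fv.layout.items():
    values = np.round(fv.values[start:end], 3)
    print(f"{block:>5} [{start:3d}:{end:3d}]  {values}")
# SPC is a 4-slot one-hot per residue (hydrophobic / polar / + / -);
# pads 'X' are all-zero.  VDWV and ASA are per-residue magnitudes in
# [0, 1].  PWAA sums signed distance weights per amino acid: negative
# components mark upstream occurrences, positive ones downstream, and
# residues hugging the center contribute least.
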