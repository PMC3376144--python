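"""Generate a synthetic methylation dataset and build peptide windows.

The generator plants three class differences around each positive
arginine: a glycine motif at offsets -1/+1/+2 (mimicking the
glycine-rich context of methylarginine), smaller side-chain volumes in
the flanks, and elevated solvent exposure.  Everything else is uniform
background, so the planted signal is the only thing a classifier can
learn.
"""

from methylpred import build_bundle, make_fixture

dataset = make_fixture("small", signal=True, seed=0)
print(f"proteins:        {len(dataset.proteins)}")
print(f"positive sites:  {len(dataset.sites)}")
print(f"all R centers:   {len(dataset.truth)}")

bundle = build_bundle(
    dataset.proteins, dataset.sites, residue_type="R", ratio=1, n_sets=5, seed=0
)
print(f"positive windows:       {len(bundle.positives)}")
print(f"negative replicate sets: {len(bundle.negative_sets)} "
      f"x {len(bundle.negative_sets[0])} windows")
w = bundle.positives[0]
print(f"example window:  {w.sequence}  (center {w.center_residue}, "
      f"protein {w.protein_id}, position {w.position})")
# The 15-mer is the unit every downstream step consumes: the center is the
# candidate site, 'X' marks padding beyond the protein's termini, and the
# five negative sets are independent 1:1 subsamples of the unannotated
# arginines used to average out sampling luck.
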