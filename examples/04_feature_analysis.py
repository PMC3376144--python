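"""Positional analyses: what distinguishes methylated from background sites.

Computes, per offset from the candidate arginine: the hydrophobic-group
fraction, the mean van der Waals volume, the mean solvent exposure, and
Welch's t-test of the class difference at the planted +1 offset.
"""

from methylpred import make_fixture, read_property_table
from methylpred.analysis import (
    frequency_matrix,
    group_enrichment_test,
    group_fraction_profile,
    numeric_profile,
)
from methylpred.dataset import deduplicate, enumerate_candidates

dataset = make_fixture("standard", signal=True, seed=0)
pos, neg = enumerate_candidates(dataset.proteins, dataset.sites, "R", L=7)
reduced = deduplicate(pos + neg)
pos = [w for w in reduced if w.label == "positive"]
neg = [w for w in reduced if w.label == "negative"]
table = read_property_table()

g1_pos = group_fraction_profile(pos, table, label="positive")[1]
g1_neg = group_fraction_profile(neg, table, label="negative")[1]
print("offset  G1(pos)  G1(neg)   <- hydrophobic-group fraction")
for k, offset in enumerate(g1_pos.offsets):
    if -2 <= offset <= 2:
        print(f"{offset:>+6d}  {g1_pos.values[k]:.3f}    {g1_neg.values[k]:.3f}")

r = group_enrichment_test(pos, neg, table, group=1, offset=1)
print(f"\nWelch test, hydrophobic enrichment at +1: "
      f"t = {r.statistic:.1f}, p = {r.p_value:.2e}")

vdwv = numeric_profile(pos, "VDWV", table, label="positive")
print(f"mean VDWV at +1 (positives): {vdwv.values[8]:.3f}")
freq = frequency_matrix(pos)
print(f"glycine frequency at +1 (positives): {freq.loc['G', 1]:.3f}")
# The planted glycine motif shows up as a hydrophobic-group excess and a
# volume depression next to the methylated arginine — glycine is both
# the smallest residue and a member of the hydrophobic group — exactly
# the positional signature these profiles are built to surface.
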