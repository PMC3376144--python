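# Methods

## Problem and model

Given a protein sequence and the residue type of interest (R or K),
every occurrence of that residue is a candidate methylation site.
Candidates are represented as symmetric peptide windows of `2L+1`
residues (default `L = 7`, window 15 — the size at which flanking
context is informative without diluting the local signal; 9–19 are
accepted for window-size studies). Positions beyond the protein termini
are padded with `X`, which contributes zero in every feature block, so
the vector length is fixed by `L` alone. Ambiguity codes (B, J, O, U,
X, Z) are tolerated in input sequences and treated exactly like pads —
the least-assumption choice for residues whose identity is unknown.

A window is encoded as the concatenation of up to four blocks in the
fixed order SPC, VDWV, PWAA, ASA (canonical order makes model
serialization and the ablation study unambiguous):

* **SPC** — per-residue one-hot of the four-group physicochemical
  partition (hydrophobic / polar / positively charged / negatively
  charged). The partition is fixed by the coding scheme's definition
  and the loader rejects property tables that deviate from it.
* **VDWV** — the normalized van der Waals volume of each residue. The
  packaged table transcribes the Fauchère side-chain volume scale
  rescaled to the unit interval (glycine 0, tryptophan 1); values are
  used exactly as tabulated, with no dataset-dependent rescaling.
* **PWAA** — 20 components; component *i* is
  `(1/(L(L+1))) Σ_j x_ij (j + |j|/L)` over offsets `j ∈ [−L, L]`.
  Zero-sum note: the weight is antisymmetric up to the `|j|/L` term, so
  a fully occupied window's components always sum to `1/L` regardless
  of composition — a conservation property the tests exploit.
* **ASA** — per-residue percent solvent exposure divided by 100. The
  fixed affine map was chosen over dataset min-max normalization so
  that a peptide's features never depend on the batch it is scored
  with. ASA is consumed from files (or the generator); predicting it is
  out of scope. A window from a protein without an ASA track encodes as
  zeros with a logged warning rather than an error, so structural data
  remains optional at prediction time.

With all blocks and window 15 the vector is 110-dimensional and every
component lies in [0, 1], which is why no per-feature standardization
is applied before the SVM.

## Dataset construction

Annotated sites are positives; every other residue of the same type in
annotated proteins is a presumed negative. Redundancy reduction keeps
the first of any identical (sequence, label) peptide pair, and a
peptide occurring with both labels is resolved in favor of the positive
— the negative label merely means "not annotated" and is the less
trusted of the two. Protein-level homology reduction below exact
identity is an upstream responsibility (an exact-duplicate protein
filter is provided).

Because negatives outnumber positives roughly tenfold, training sets
are built by drawing negatives uniformly without replacement at a
chosen positive:negative ratio (default 1:1, the ratio at which
sensitivity and specificity balance). Five independent replicate draws
are taken by default and every reported metric is the mean ± sample
standard deviation across replicate runs, so sampling luck is visible
rather than hidden.

## Classifier and evaluation

The classifier is an RBF-kernel SVM (scikit-learn's libsvm binding).
Defaults `C = 8`, `γ = 2⁻⁵` are a mid-grid point of the canonical
coarse grid `C ∈ {2⁻⁵…2¹⁵}, γ ∈ {2⁻¹⁵…2³}` appropriate for
~100-dimensional unit-scaled features; `grid_search` tunes on that grid
by stratified CV accuracy with ties broken toward the smaller `(C, γ)`.
The decision threshold is fixed at 0; raw decision values are returned
for downstream use. Tuning, when requested, happens once per
negative-set replicate rather than inside every fold — cheaper, and the
replicate averaging already guards against a lucky tune.

Metrics are Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total and
the Matthews correlation coefficient. Degenerate denominators follow
the standard convention: undefined Sn/Sp report 0 with a warning, MCC
with a zero factor under the root is 0.

Cross-validation is stratified by class (fold class-sizes differ by at
most one) and seeded. Within one replicate, confusion counts are pooled
across folds before metrics are computed; per-fold metric sets are also
recorded. Pooling makes `k = n` exactly equivalent to leave-one-out
validation — the test suite verifies prediction-for-prediction equality
against an explicit hold-one-out loop. The independent-test protocol
refuses any protein shared between training and test data, trains one
model per negative-set replicate and pools the replicate models'
confusion counts.

## Positional feature analysis

Per-offset analyses exclude pads from every denominator: group
fractions (summing to 1 across the four groups), mean ± sd profiles of
VDWV and ASA, and a column-normalized 20-row amino-acid frequency
matrix in position-weight-matrix layout for logo renderers. Class
differences are assessed with Welch's unequal-variance t-test
(Welch–Satterthwaite degrees of freedom, two-sided p). The unpaired
Welch test is used deliberately: positive and negative windows are
independent samples, not matched pairs, so a paired test would be
incoherent here. For group or residue enrichment at an offset, each
window contributes a binary membership indicator as its sample value.
Degenerate inputs (samples smaller than 2, zero variance on both sides
with unequal means) are flagged in the result rather than raised.

## Synthetic data generator

The generator is first-class, tested code: it produces proteins,
annotations and ASA tracks in exactly the package's file dialects, with
a truth manifest partitioning all centers. Background sequences are
uniform over the 20 standard residues — the simplest exchangeable null,
chosen so that with all signals off the two classes are
indistinguishable by construction. Three class differences are planted
around each positive center, each independently controllable:

* a motif (default glycine at offsets −1, +1, +2, emulating the
  glycine-rich context characteristic of methylarginine), planted
  per-offset with probability `p_signal`;
* a side-chain volume depression: non-motif flank residues within ±3
  are resampled from the small-volume half of the VDWV table with
  probability `vdwv_shift` (default 0.5);
* a solvent-exposure shift: ASA is drawn from a truncated normal on
  [0, 100] with mean 45 within ±7 of positives versus 30 elsewhere
  (sd 10).

Positive centers are drawn uniformly from all centers, with the single
constraint that two positives lie further apart than the widest motif
offset so planting one positive's flanks can never overwrite another
positive center. That constraint concerns only the relative placement
of positives and leaves no trace in any window-encodable feature, so
the `p_signal = 0`, equal-ASA, no-shift configuration is an exact null.

Two profiles fix the study conditions: `small` (30 proteins of 150–250
residues, 50 positives) for fast tests, and `standard` (120 proteins of
500–700 residues, 300 positives, ≥3000 background centers) emulating
the scale of a curated methylarginine training set. These sizes were
chosen once as a realistic desk-scale benchmark.

What the generator does **not** emulate: natural amino-acid background
frequencies, homologous protein families, enzyme-family substrate
specificity beyond the planted motif, correlated ASA along the chain,
or label noise in the negatives. Passing the synthetic benchmarks
therefore demonstrates that the pipeline recovers planted signal of the
kind reported for real methylation data and finds nothing in its
absence — not that any particular real-data accuracy will be achieved.

## Numerical and reproducibility notes

* All randomness flows from explicit integer seeds; replicate draws,
  fold splits and the generator are reproducible byte-for-byte.
  Stage-level child seeds are derived with numpy's `SeedSequence`.
* The PWAA implementation and its test oracle accumulate the raw
  weights and divide once by `L(L+1)`, making the two bit-identical.
* libsvm's dual solver is deterministic for fixed input order;
  permuting training rows can move decision values within the solver's
  convergence tolerance (~1e-3), which the tests treat as the
  determinism contract's resolution.
* Model files carry a format version and refuse to load across
  incompatible versions; a loaded model only scores inputs whose
  feature layout matches the one recorded at training time.

## Known limitations

* The exact-identity peptide filter does not substitute for 40 %
  protein-identity clustering; inflated estimates are possible if
  homologous proteins enter the pipeline.
* MCC/Sn/Sp on very small folds are noisy; pooled-count reporting
  mitigates but does not remove this.
* ASA quality is inherited from whatever upstream predictor produced
  the track; the encoder applies no error model.
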