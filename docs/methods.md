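# Methods

## Scope and model

`tmstruct` is a multi-task sequence labeller for α-helical transmembrane
proteins.  Its unit of data is one protein chain in membrane-oriented
coordinates: the structure is rotated/translated so that the z-axis is the
membrane normal and z = 0 the bilayer centre (the OPM convention).  The
membrane half-thickness h is an input per chain (default 15.0 Å; real
bilayers vary by roughly ±1 Å around that), never a hard-coded constant.

Ten per-residue targets are derived from coordinates, B-factors and DSSP
output, and predicted jointly by an ensemble of five model families blended
across five cross-validation folds.  Related targets share one network:
{z, topology}, {continuous, two-state flexibility}, {φ, ψ}, {three RSA
variants}, and secondary structure alone — five groups, hence 15 networks
across the three network types, and 5 folds × (5 base + 1 meta) = 30 models
behind each group in the final predictor.

## Target derivations and their edge cases

**Depth (z).**  Cα z clipped to ±25 Å then divided by 25.  The clip reflects
that depths beyond the bilayer carry no membrane signal; clipping before
scaling makes the scaled target exactly ±1 at the bounds.

**Topology.**  With h the half-thickness: (1) maximal runs of |z| ≤ h whose
two ends lie on opposite membrane sides within 10 Å of their respective
boundaries are transmembrane segments — because the runs are maximal under
|z| ≤ h, this single step already realises "extend while touching the
membrane"; (2) remaining in-membrane runs flanked on both sides by
same-side out-of-membrane residues, of length ≥ 3, whose deepest residue
satisfies |z| ≤ h − 3 (≥ 3 Å immersion) are re-entrant regions; (3) all
other residues are inside (z < 0) or outside (z ≥ 0).  The annotation is
exactly equivariant under z ↦ −z with inside↔outside swapped (for nonzero
z).  Known limitation: a run that crosses the centre twice without leaving
the membrane (one deep V-shaped dip) has same-side ends and is judged by
the re-entrant rule, which rejects it if the dip approaches the far
boundary closer than 3 Å; such traces do not occur in the generator and are
pathological in real data.

**Flexibility.**  B-factors are comparable only within one structure, so
B_norm is the per-chain population z-score; chains with fewer than two
distinct B-factors are rejected upstream.  The two-state variant is
flexible ⇔ B_norm > 0.03 (the boundary value itself is rigid).

**Torsions.**  φ(i) = dihedral(C(i−1), N(i), Cα(i), C(i)),
ψ(i) = dihedral(N(i), Cα(i), C(i), N(i+1)), signed per the standard
convention (cross-checked against Biopython/biotite/MDAnalysis to 1e-11
degrees), range (−180°, 180°], scaled by 1/180.  Masks are false at chain
termini and across breaks, detected as C–N distances above 2.5 Å (a peptide
bond is ~1.33 Å); masked residues are excluded from losses and metrics.

**Secondary structure and RSA.**  DSSP 8-state collapsed to
helix/sheet/coil; RSA = ASA / max-ASA with the theoretical maximum-ASA
scale (Tien et al. 2013) shipped as an overridable table, capped at 1.0
because DSSP occasionally exceeds the tabulated maxima.  The RSA change
(monomer − complex) is floored at 0 — complexation can only bury surface —
with the raw difference retained in the bundle diagnostics.

## Features

One-hot rows for the 20 standard residues (alphabetical one-letter order);
non-standard letters give all-zero rows and are excluded from profile
counts.  The profile is m_ij = σ(log(p_ij/p_i)) with count-level
pseudocounts: p_ij = (c_ij + 1)/(n_j + 20) and p_i = (c_i + L)/(N + 20L),
where n_j is the non-gap count of column j, N the total non-gap count, L
the alignment length.  Phrasing pseudocounts on frequencies is not
well-formed (adding 1 to a probability), so they are applied to counts with
correspondingly augmented denominators; the two pseudocounts stay mutually
consistent because adding one count to a column cell adds L alignment-wide.
Consequences worth knowing: entries are strictly inside (0, 1) for any MSA
including all-gap columns; a residue with p_ij = p_i scores exactly 0.5; a
residue absent from the alignment scores below 0.5 in columns at least as
deep as the alignment average (exactly 0.5 in the gap-free uniform-depth
limit), and the matrix is not exactly invariant under duplicating all rows
— duplication doubles counts but not pseudocounts, so repeated duplication
converges monotonically towards the pseudocount-free log-odds profile.
The query is row 0 of the MSA and is included in the counts.

## Dataset filters and splits

Filters, applied in order with machine-readable reason codes: X-ray
resolution ≤ 3.5 Å; length ≥ 30; more than one amino-acid type; more than
one distinct B-factor; complete N/Cα/C backbone; atomseq covering ≥ 80% of
seqres; missing residues only at the termini; at least one Cα on each side
of the membrane centre.

Redundancy reduction is greedy longest-first clustering: records sorted by
length (id as tie-break) join the first representative above the identity
threshold (0.4) or found a new cluster.  Sequence identity is
identities/alignment-length under a global alignment with match 1,
mismatch 0, gap −1 (Biopython's pairwise aligner); a precomputed
two-column cluster file can replace it.  The exact cluster membership of an
external tool is not reproduced — downstream code relies only on the
invariant that no retained pair exceeds the threshold.

The hold-out split draws ⌊0.1·stratum⌋ records per topology stratum
(number of TMS, capped at 14+), with a minimum of one when the stratum is
large enough; the cross-validation pool is then purged of >30% identity to
the test set.  Folds: records dealt round-robin into five
topology-stratified bins; per fold, the other bins are purged against the
test bin, split 90/10 into train/validation (stratified; if tiny strata
round every validation draw to zero, one record is held out so validation
is never empty), and train is purged against validation.  Splitting before
purging mirrors the fold-level order of operations; fold sizes may differ
after purging.

## Models

All three network types share one trunk: an embedding maps one-hot rows to
n_embedding reals (learned amino-acid properties), concatenated with the
profile into L×(20+n_embedding); a hidden stack; window-1 dense layers;
one head per group target with linear/sigmoid/softmax output and the
matching squared-error / binary / categorical cross-entropy loss, summed
with equal weights (multi-task weighting left uniform deliberately — at
desk scale there is no signal to tune it on).  Hidden stacks: plain
convolutions (ReLU; receptive field 1 + n·(w−1)); dilated blocks of
n_dconv_layers convolutions with dilation 2^(l−1) (receptive field grows
exponentially while parameters grow linearly); bidirectional LSTMs whose
two directions' hidden states pass through tanh and concatenate (receptive
field: the whole sequence).  Residual connections either add (with a
window-1 projection wherever widths differ, in particular at the first
hidden layer) or concatenate the unit's input to its output.

The networks are implemented in NumPy with hand-derived backward passes,
verified against central finite differences to ~1e-9 relative error for
all three hidden types.  Training uses Adam; a batch accumulates gradients
over `batch_size` variable-length sequences before one update — this is
mathematically identical to the padded-batch formulation (masks already
exclude invalid residues from every loss term) and avoids padding logic
entirely.  One "iteration" is an epoch; after 5 epochs without validation
improvement the learning rate is multiplied by 0.1, after 10 the training
stops, and the best-validation-epoch weights are restored.  Weight
initialisation is seeded fan-in-scaled Gaussian (He-style for ReLU
layers).

Tree models see explicit windows: row i of the windowed design matrix
concatenates feature rows i−(w−1)/2 … i+(w−1)/2, zero-padded at the
termini.  Random forests (scikit-learn; squared error / Gini) are
grid-searched exhaustively over feature fraction, minimum leaf size and
window, with the tree count grown in steps of 100 until the validation
score stops improving.  Gradient boosting (xgboost) uses a seeded random
search over window, column/row subsampling, learning rate, depth, γ and
minimum child weight, with validation early stopping.  Tree models are
fitted per target (trees have no shared trunk to amortise); degenerate
single-class training labels fall back to a constant predictor.

Hyperparameter candidate lists are configuration, not constants: the
defaults span small layer counts, neuron counts, window sizes, residual
modes and embedding widths chosen to train in seconds on one CPU.

## Blending

Per fold and target, a meta-model is fitted on the base families'
validation-bin predictions: ridge regression with α = 1e−6 for continuous
targets (least squares in effect; the tiny penalty keeps constant
predictor columns — common at desk scale — well-posed) and (multinomial)
logistic regression for discrete ones, with 5K inputs for a K-class
target.  Since the meta design contains each base model as a feasible
solution, its in-sample error never exceeds any single family's.  The
final prediction averages the five fold meta-models' outputs and
renormalises categorical rows to sum to one; averaging probabilities
(rather than argmax votes) preserves calibration information.

## Evaluation

Continuous targets: MAE, MSE, RMSE, Pearson and Spearman (midranks for
ties); depth errors reported in Å, angle errors in degrees using the
circular difference min(|Δ|, 360−|Δ|) — flagged "circular" in the report
since a naive linear difference would double-count wrap-around errors.
Discrete targets: standard accuracy (TP+TN)/total, per-class precision,
recall, F1, Matthews correlation (NaN where a denominator vanishes, never
an exception) and a rank-statistic ROC AUC (ties 0.5).  Multi-class
accuracy compares argmax labels, ties broken toward the lowest class
index.  Secondary structure is additionally scored on non-membrane
residues only: transmembrane stretches are almost uniformly helical, so
including them inflates accuracy.

## Synthetic data: what it emulates and what it does not

The generator emulates the pipeline's input universe: membrane-crossing
z-traces with loops ~5 Å outside the boundary, crossings interpolating
linearly between ∓(h−0.5) Å, and re-entrant hairpins descending a seeded
4–10 Å past the boundary; full N/Cα/C backbones laid out along the trace
with rotating lateral offsets (torsions well defined everywhere, no
spurious chain breaks; the construction's computed φ/ψ are recorded as
truth rather than asserted equal to textbook helix values); B-factors
rising outside the membrane plus Gaussian noise; sequences drawn from
depth-dependent pools — hydrophobic in the bilayer, polar in loops, with
K/R-enriched inner loops versus D/E-enriched outer loops encoding the
positive-inside rule so that inside and outside are distinguishable from
composition; mutated-copy MSAs; and directly supplied secondary-structure
and accessibility truth (helical membrane segments; no DSSP emulation).
Coordinates are rounded to PDB precision at construction so file
round-trips are exact.

Default study conditions: learnable datasets of ≥ 10 chains with 1–4
crossings, re-entrant regions at rate 0.2 per crossing, lengths 50–300,
MSAs of 8 rows at 15% per-site substitution, resolution 2.0 Å.  All
randomness flows from one seeded generator.

What passing tests do and do not show: the fixtures prove the machinery —
derivations invert the generator, splits respect identity constraints,
models extract a planted composition signal far above a label-permuted
control, blending never trails its worst input.  They do not calibrate
real-world accuracy: real chains have correlated evolutionary profiles,
non-ideal geometry, interface-specific burial patterns and much weaker
label-composition coupling, so accuracy numbers on fixtures are upper
bounds of convenience, not benchmarks.

## Numerical choices

Population (not sample) statistics for B-factor z-scores; dihedrals via
the atan2 formulation (no arccos near-collinearity loss); softmax rows sum
to 1 within 1e-6; cross-entropies clamped with ε = 1e-12; Adam defaults
β = (0.9, 0.999), ε = 1e-8; identity purging uses strict ">" against the
0.3 threshold; greedy clustering ties broken by record id; random search
ties keep the earliest draw; PDB fixed-column parsing keeps altloc blank
or 'A', residues in file order (insertion codes included), first model
only for multi-model entries; empty inputs yield empty outputs for
annotation and encodings, and errors for statistics that need data.

## Problem sizes

Unit and property tests run on chains of 50–300 residues and datasets of
10–50 chains; the split-invariant suite checks 100 seeded datasets of 12
lightweight records; the learnability experiment trains a 2-layer,
16-neuron, window-7 convolutional network on 40 chains for up to 15
epochs.  These sizes were chosen so the whole suite trains dozens of
models in about a minute on one CPU while still leaving each claim
statistically unambiguous (the learnability margin is ~0.4 accuracy
against the control, twice the asserted bound).
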