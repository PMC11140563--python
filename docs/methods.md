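# Methods

This note documents the models implemented in `abspatial`, the choices made
where the design was genuinely open, and what the synthetic validation suite
does and does not establish.

## Spatial scores

Both scores are computed per atom on one structure snapshot and then summed
over ten regions of the antibody variable fragment: the six Chothia CDR
loops (CDRH1–3, CDRL1–3), their union (CDR), the heavy and light variable
domains (Hv, Lv) and the whole Fv.

**Spatial charge map (SCM).** A residue is *exposed* when its summed
side-chain solvent-accessible area is at least 10 Å² (inclusive). The atomic
value is

    SCM_i = Σ_j q_j ,   over atoms j ≠ i of exposed residues with d(i,j) ≤ 10 Å,

with q_j the partial charge. Region scores split the field by sign,

    SCM_pos(D) = Σ_{i∈D} SCM_i·H(SCM_i),
    SCM_neg(D) = Σ_{i∈D} |SCM_i|·H(−SCM_i),

with H the Heaviside step, H(0) = 0, so both are non-negative. An atom
belongs to a region when its residue does; residues are never split.
Choices worth noting: atom *i* itself is excluded from its own
neighbourhood sum (`include_self` restores it); all atoms of an exposed
residue contribute, not only side-chain atoms; the field is computed for
every atom by default (`restrict_to_exposed` limits it to atoms of exposed
residues).

**Spatial aggregation propensity (SAP).** For atom *i*,

    SAP_i = Σ_r [ SAA(side-chain atoms of r within R of i) / SAA_ref(r) ] · φ(r)

over residues r with at least one side-chain atom within R of *i*.
SAA_ref(r) is the fully-exposed side-chain area of the residue type
(Gly-X-Gly standard-state values after Miller et al. 1987) and φ the
hydrophobicity (Black & Mould 1991 scale normalised to [0, 1] and anchored
at glycine = 0, so hydrophilic residues are negative). Region scores keep
the positive part only. The radius R is a required configuration value with
default 10 Å (matching the SCM cutoff); 5 Å is the common small-patch
alternative. Because every in-range side-chain atom contributes its own
SASA weighted by its residue's φ/SAA_ref, the residue-grouped definition
collapses to an atom-level weighted sum, which is how the engine vectorises
it; the test suite checks the engine against a literal residue-by-residue
implementation.

**Ensemble statistics.** Scores are computed per snapshot (MD frame or
PDB MODEL block) and summarised as mean, population standard deviation
(denominator N) and relative standard deviation std/|mean|. A zero mean
with non-zero spread yields NaN (an explicit "undefined" sentinel), never
infinity. Exposure is evaluated per frame by default; a config flag
switches to classifying exposure from the ensemble-mean side-chain SASA.

## SASA

Shrake–Rupley with a deterministic golden-section spiral lattice
(default 960 points, probe 1.4 Å), so results are bit-reproducible. A test
point lying exactly on another atom's solvent-expanded sphere counts as
buried. An isolated atom therefore scores exactly 4π(r+w)². Doubling the
lattice density changes per-atom values by well under 1% on the bundled
fixtures; a latitude-band brute-force implementation agrees within
point-sampling tolerance (≈2%).

## Structure model and parameter tables

PDB input/output goes through gemmi; MODEL/ENDMDL blocks are the snapshot
interface and all snapshots must share an identical atom composition.
Partial charges come from a bundled condensed heavy-atom table: hydrogen
charges are folded into their bonded heavy atom, polarity patterns follow
the CHARMM36 protein topology, and per-residue sums are exactly the formal
charge (0, ±1). This makes hydrogen-free antibody models directly scorable,
which is the common case for homology-model inputs; structures that do
carry hydrogens are handled in permissive mode (unparameterised atoms are
skipped and logged). Histidine is always assigned its doubly-protonated
(+1) form — the fixed-protonation convention for the mildly acidic
formulation conditions (pH ≈ 6) this score family targets. Radii are the
Bondi van der Waals set, keyed by element. Backbone atoms are
{N, CA, C, O, OXT} plus backbone hydrogens; glycine's HA2/HA3 count as side
chain so its side-chain SASA is defined (its SAP contribution is still zero
through φ(Gly) = 0). N-/C-terminal charge patches exist but default off, so
the per-residue formal-charge invariant holds for every residue.

## Sequence preprocessing

Chains are placed into fixed Chothia slot templates — 145 heavy and 127
light positions, CDR loops carrying the insertion slots (CDRH3 holds at
most 30 residues) — and unoccupied slots are padded with dashes. The
numbering interface is pluggable: the bundled `ChothiaTemplateNumberer` is
a deterministic template filler for canonical-length chains (all length
variation in CDR3), sufficient for synthetic repertoires and tests;
production pipelines can wire in a full annotator.

Filters accumulate reason codes rather than short-circuiting: DUPLICATE
(exact heavy+light string match against the running set), UNPAIRED,
NUMBERING_FAIL, CDRH3_TOO_LONG (> 30 residues in the scheme's CDR3 window),
INSERTION (insertion-coded positions outside CDR3), CYS_MISSING (conserved
cysteines at the scheme's positions: Chothia H22/H92 and L23/L88; IMGT
23/104). Extra cysteines elsewhere are logged, and fatal only in strict
mode. Filtering runs on the numbering, before template placement, so an
over-long CDR3 is reported as CDRH3_TOO_LONG rather than as an alignment
failure.

One-hot encoding concatenates heavy-then-light (272 positions) over 21
channels: the 20 amino acids in alphabetical one-letter order, gap last.
Any fixed order is equivalent for training; this one is asserted in tests
and documented here.

## CNN surrogate

Three models — one per property (SAP_pos, SCM_neg, SCM_pos) — each map the
272×21 encoding to the ten region scores. Architecture:
[conv1d(ReLU) → batch-norm → dropout] × 3 → pooling (max by default,
width 2; average selectable) → flatten → dense(ReLU) → linear(10). Training
uses Adam, batch 32, a 65/25/10 train/validation/test split, MAE loss by
default (MSE selectable), and keeps the weights from the epoch of minimum
validation MAE. The hyperparameter grid is filters 16–128 (step 16),
kernel ∈ {3,4,5}, dropout 0–0.5 (step 0.1), dense units 32–128 (step 16),
learning rate ∈ {1e-2, 5e-3, 1e-3, 1e-4}; random search, successive-halving
hyperband and Gaussian-process Bayesian optimisation are provided as
tuners. Models persist as a JSON architecture descriptor plus HDF5 weights.

The network is implemented directly on numpy (im2col convolutions,
analytic backprop verified against finite differences). One numerical
choice matters and is exposed as `TrainingRun.bn_freeze_epoch`: one-hot
sequence activations have tiny post-ReLU per-channel variances, and
normalising by them places downstream layers in a badly conditioned regime
that, at the sample sizes this engine targets, memorises without
generalising (larger batches make it worse, so it is not statistics
noise). By default (`bn_freeze_epoch = 0`) the batch-norm layers stay
frozen at their identity initialisation — the trainable per-channel
scale/shift remain — which restores stable generalisation; `None` runs
conventional live batch statistics.

## Synthetic data: what it emulates, and what it does not

* **Toy structures** are single-atom "residues" at hand-picked separations
  with explicit charges and radii, so SCM values follow from direct
  summation and isolated-atom SASA/SAP from closed forms. The analytic
  sheets are computed by independent direct summation, never by the engines
  under test.
* **Sequences** carry a fixed framework consensus with variation
  concentrated in the Chothia CDR positions and CDR3 length (uniform 0–10
  heavy / 0–8 light insertions), mirroring the germline conservation of
  real paired repertoires. They do not reproduce real germline usage,
  mutation spectra, or pairing biases.
* **Surrogate labels** are a fixed sparse linear map of the one-hot
  encoding: each of the ten outputs sums a random per-amino-acid weight
  over the slots of its region, reproducing the additive residue-type
  structure of the real region descriptors (composite regions overlap
  their parts, so outputs correlate, as real descriptors do). Signal is
  scaled to unit standard deviation and Gaussian noise of sd 0.1 added
  (10:1 signal-to-noise). Passing the recovery test shows the training
  stack can identify a learnable sequence→descriptor map at desk scale; it
  does not certify accuracy on MD-derived labels, whose noise structure
  and nonlinearity are different.
* **The aggregation table** is 21 antibodies × 30 descriptors: unit-variance
  Gaussian columns sharing a common factor (pairwise correlation 0.2), with
  the target a linear combination of three named descriptors (coefficients
  1.0, −0.8, 0.6) plus Gaussian noise (sd 0.3). This emulates the shape and
  the correlated-feature hazard of the real small-data regression, not its
  actual descriptor distributions.

## Regression workflow

Exhaustive feature selection enumerates every size-k descriptor subset and
scores it by mean MSE under repeated k-fold CV (defaults: 4 folds per the
original workflow, 5 repeats — the repeat count is this package's choice —
seeded). Ranking ties break lexicographically on sorted feature names. The
linear family runs through a fast least-squares path in the hot loop
(verified in tests to match the scikit-learn route to 1e-9); KNN/SVR/RF go
through scikit-learn estimators. Hyperparameter grids are bounded to
neighbours 2–8, SVR C ∈ [5, 15] and ε ∈ [0.1, 0.5], and forest depth 2–6;
tuning selects by LOOCV MSE by default (k-fold selectable). Features are
standardised inside every fold for the distance/kernel families (KNN, SVR)
and left raw for linear and forests. Pearson correlation is used
throughout; a constant target yields NaN. The reliability rule accepts a
model when the fit-to-LOOCV correlation drop is at most 0.3 (inclusive).

## Problem sizes in the validation suite

The bundled checks run at desk scale by design: oracle comparisons on
10–20-atom clusters, surrogate recovery at n = 2000 sequences and 90
epochs, feature-selection recovery over 25 generator seeds. These sizes
are where the properties under test are already decisive (oracle
equivalence is exact at any n; the recovery tasks are identifiable but not
trivial at these n).

## Known limitations

* The bundled numberer handles template-compatible (canonical-length)
  chains only; real repertoires need an external annotator behind the
  numbering interface.
* The charge table is a condensed heavy-atom set, not a full all-atom force
  field; absolute SCM values differ from an all-atom evaluation by the
  within-residue dipole detail, though sign structure and region sums track
  it closely.
* Sampling-based SASA only; no analytic surface.
* The CNN engine is CPU-bound numpy: fine for thousands of sequences,
  not for repertoire-scale (10^5+) training.
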