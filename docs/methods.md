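# Methods

## Problem setting

Antihypertensive peptides (AHTPs) are short peptides (here: length ≥ 5,
standard 20-residue alphabet) that inhibit angiotensin-converting enzyme or
otherwise lower blood pressure. The package frames AHTP discovery as binary
classification of peptide sequences against "background" peptides that
resemble random protein fragments, with the decision made by a heterogeneous
ensemble over a rich, fully named descriptor vector.

## Descriptor vector (431 components)

All blocks are deterministic functions of the sequence. Two residue
orderings are used: alphabetical one-letter order (A…Y) everywhere except
the quasi-sequence-order block, which uses alphabetical three-letter order
(Ala…Val, placing Tyr at index 19). This mixed convention is what makes the
documented name anchors come out right (APAAC1_15 = Arg, Pse_PC13 = Pro,
QSO19 = Tyr) and is frozen into the versioned, hashed schema.

* **AAC (20)** — residue fractions.
* **Pseudo-compositions (23 + 22 + 26 + 23 + 23)** — type-I
  pseudo-composition over the Chou property triple (Eisenberg
  hydrophobicity, Hopp–Woods hydrophilicity, side-chain mass) with λ = 3,
  w = 0.05 (PAAC); a parallel-correlation variant with λ = 2 (its 22-dim
  layout fixes λ); a series-correlation variant interleaving
  hydrophobicity/hydrophilicity terms per lag (λ = 3, 26 dims); and two
  amphiphilic blocks using a single-property correlation function each.
  *Design choice:* every correlation function, including the amphiphilic
  blocks, uses squared differences of alphabet-normalised (zero-mean,
  unit-variance) properties. The classical amphiphilic formulation uses
  property *products*; the squared-difference form was chosen so that all
  coupling terms vanish exactly on homopolymers, which gives every mode the
  same clean degeneracy contract. Each mode's components sum to 1.
* **C/T/D (21 + 21 + 105)** — for seven properties (hydrophobicity, van der
  Waals volume, polarity, polarizability, charge, secondary structure,
  solvent accessibility) the alphabet is partitioned into the standard
  three groups (e.g. polarizability group 1 = {G,A,S,D,T}; buried solvent-
  accessibility group = {A,L,F,C,G,I,V,W}); composition = group fractions,
  transition = unordered cross-group adjacent-pair counts over L−1,
  distribution = positions (percent of L) of the first, 25%, 50%, 75% and
  last group occurrence. The quantile index is round-half-up(q·n) with a
  floor of 1 — e.g. for five occurrences at positions 1…5 of a length-5
  peptide the five points are 20, 20, 60, 80, 100. An absent group
  contributes zeros.
* **QSO/SOCN (46 + 6)** — coupling numbers τ_d = Σᵢ d(Rᵢ, Rᵢ₊d)² for
  d = 1..3 under two packaged 20×20 distance matrices (a physicochemical
  matrix and the Grantham matrix), then per matrix the 20 normalised
  occurrences f_r/(Σf + w·Στ) and 3 weighted couplings w·τ_d/(Σf + w·Στ),
  w = 0.1. Each matrix's 23 components sum to 1.
* **Scales & indices (76)** — residue-mean projections onto nine scale
  families (Cruciani 3, z-scales 5, FASGAI 6, T-scales 5, VHSE 8, ProtFP 8,
  ST-scales 8, MS-WHIM 3, BLOSUM 8) plus: aliphatic index
  (X_A + 2.9·X_V + 3.9·(X_I+X_L) on mole-percent), twelve Geary
  autocorrelations (hydrophobicity/hydrophilicity/side-chain-mass/polarity
  scales × lags 1–3; defined as 0 for zero-variance sequences), lag-1
  auto/cross-covariances of z-scales 1–2, Boman interaction potential
  (negated mean transfer free energy), Henderson–Hasselbalch net charge at
  pH 7 and isoelectric point by bisection (Lehninger pKa set, termini
  included; the charge function is strictly decreasing so the root is
  unique), instability index (Guruprasad dipeptide weights via biopython),
  and Eisenberg hydrophobic moments at window angles 100° and 160°.
* **Motif counts (13)** — overlapping occurrence counts of a selected motif
  set; the default is the top log-odds-enriched 2-mer plus twelve 3-mers
  (YP, HLP, IYP, LHL, LPP, LRP, VPP, PEV, PFP, QTP, VLP, VYP, YPF). Counts,
  not binary flags: counts carry strictly more information and reduce to
  flags downstream.
* **Propensities (6)** — aggregation, amyloid, turn, α-helix, helical
  aggregation and β-strand tendencies from a provider interface. The
  built-in surrogate scores aggregation as the mean over length-5 windows
  of max(0, mean Kyte–Doolittle hydropathy) and conformation tendencies as
  mean Chou–Fasman preferences (products thereof for the two aggregation
  cross-terms). It is a deliberately simple, deterministic scorer of the
  same six quantities an external statistical-mechanics propensity program
  would produce — not a reimplementation of any such program — and a zero
  provider ablates the block.

### Packaged tables and provenance

Shipped as versioned TSVs under `ahtpscreen/data/`. Genuine published
values: the Chou property triple, Sandberg z-scales, Chou–Fasman
preferences, Kyte–Doolittle, Lehninger pKa, and the Grantham distance
matrix (recomputed from Grantham's composition/polarity/volume properties
and distance formula; spot-checked against published entries). Constructed
stand-ins, marked `synthetic` in the file name and header: the
physicochemical distance matrix (Euclidean distance over the z-scored Chou
triple, max-normalised) and the Cruciani/FASGAI/T-scale/VHSE/ProtFP/
ST-scale/MS-WHIM factor tables (deterministic rotated PCA scores of a
20×10 physicochemical property matrix with each family's published
dimensionality). The BLOSUM descriptor block is computed at load time as
the first 8 PCA score components of BLOSUM62. Statements about individual
scale components (e.g. "fasgai4 reflects composition") therefore do not
transfer to the synthetic tables; only their dimensionality and rough
character do.

## Composite features

A composite feature is the linear predictor of a logistic regression,
`β₀ + Σ βⱼ·xⱼ`, over a handful of named descriptors; it is appended to the
schema and treated as an ordinary feature. The frozen `comF`/`comF2` specs
are data (JSON), not code, mirroring their published coefficients
digit-for-digit. The `hydrophobicity` term of comF is not a schema name;
it is bound to the Eisenberg-scale residue mean — an interpretation, since
the defining scale was not recorded with the equation. `comF2`'s CTDD49
enters on its raw percent scale. New composites are fitted with a light
ridge penalty (strength 1e-4) for numerical stability; `regularization=0`
requests a pure maximum-likelihood fit, and perfect separation is reported
(diverging-coefficient flag) rather than silently truncated.

## Feature selection

**ReliefF** (k = 10 neighbours, Manhattan distance on min-max-scaled
features, equal-opportunity class priors) assigns each feature a weight in
[−1, 1]; the default cutoff keeps features with weight > 0. Neighbour ties
are broken by instance index; sampling (if a subsample of instances is
used) is seeded. **RFE** repeatedly drops the `step` least-important
features and refits until the target count remains — exactly
⌈(p−k)/step⌉ refits. Because an RBF SVM has no native per-feature weights,
importance comes either from a linear-SVM surrogate (squared weights;
fast, the default) or from permutation importance of the RBF model on a
held-out fold.

## Ensemble

Base models (published hyperparameters): random forest with 350 trees and
depth 12; RBF SVM with C = 36.0, γ = 0.119 on min-max-scaled inputs —
with hundreds of features this γ only leaves usable kernel values when
features live in [0,1], so the SVM estimator is a MinMaxScaler→SVC
pipeline (probabilities by sigmoid/Platt calibration on internal folds);
gradient-boosted trees with 800 rounds,
depth 10, η = 0.01, subsample 0.8 (histogram algorithm with 64 bins — a
discretisation choice for single-core speed that leaves the stated
hyperparameters untouched). The tree models consume the full
ReliefF-filtered vector (they select features internally); the SVM
consumes the RFE subset, by default ~2/3 of the filtered features.

Voting uses six non-negative class weights, stored max-normalised. The
published formula sums all six terms into one expression; it is
implemented as two per-class scores that are compared and renormalised —
the only reading that yields a classification — and the degenerate weight
sets provably reduce the ensemble to each single member. The decision
threshold is 0.5 with ties called AHTP (a screening tool favors
sensitivity). Weights are found by exhaustive search over the grid
{0, 0.1, …, 1.0}⁶ restricted to max-normalised candidates (771,561 of
1.77 M; scoring is fully vectorised), maximising the mean over 10
stratified partitions of held-out accuracy (MCC available), ties broken by
smaller norm then lexicographically. Inside `train_ensemble` the weights
are searched on an internal 25% validation split, after which the base
models are refitted on all training rows; `cross_validate` refits
selection and weights inside every training fold, so no information leaks
from test folds.

Metrics: ACC, Sn, Sp, MCC from confusion counts, with zero-denominator
metrics reported as undefined (None) except MCC, which takes the
conventional degenerate value 0; AUC via the trapezoidal ROC (equivalent
to the tie-averaged rank statistic, and tested against a brute-force
Mann–Whitney oracle).

## Synthetic data generator

Emulates the shape of real screening data: positives and background
peptides with geometric-like lengths (mean ≈ 8, truncated to [5, 30],
matching reported AHTP corpus averages of ~7.7–8.1); background residue
frequencies are average globular-protein (Swiss-Prot-style) frequencies;
the positive class multiplies P×2.0, Y×1.8, H×1.6, W×1.3 and depletes
D/E/C/M (×0.4–0.6), then renormalises — chosen so positives end up
proline-rich (upper-teens percent P once planted motifs are included,
the hallmark of real AHTP corpora) — and receives one planted motif
(YP/VP/PP/VLP) with probability 0.9 at a uniform random position. The
high default planting rate mirrors how strongly these dipeptide
signatures are enriched in real AHTP corpora (the YP 2-mer alone is
~20-fold overrepresented, and terminal proline frequencies reach
15–17%), where the large majority of positives carry at least one such
signature.
Generation is bitwise-reproducible given the seed.

What passing tests on this generator do **not** show: real AHTPs differ
from backgrounds in subtler, position-specific and chemistry-driven ways;
the generator has no notion of ACE binding, IC50, or length–activity
coupling. End-to-end accuracies on synthetic data characterise the
pipeline's correctness and learning capacity, not expected field
performance.

## Numerical choices and degenerate inputs

* Validation: nonstandard residues (B, J, O, U, X, Z) are rejected, never
  imputed — every descriptor table covers exactly the 20 standard
  residues. Minimum length defaults to 5 with a hard floor of 4 (lag-3
  coupling terms need length > lag).
* Pseudo-counts: k-mer and terminal log-odds use additive smoothing
  (default 0.5) with vocabulary-size scaling (V = 20^k, or 20 per terminal
  position), keeping every score finite. Motif ranking ties break
  lexicographically.
* pI bisection runs to |charge| < 1e-4 on [0, 14].
* Feature CSVs are written with 17 significant digits and read with
  round-trip float parsing, so matrix round trips are bitwise exact.
* Reproducibility: every stochastic step (generator, ReliefF sampling,
  data splits, base models, weight search) takes an explicit seed; base
  models run single-threaded.

## Test and demonstration problem sizes

The shipped test suite exercises the full pipeline at 2000 peptides per
class (with a label-shuffled control at the same size), fits recovery
checks at n = 5000, and oracle comparisons at n ≤ 50 where the reference
implementation is quadratic. Example scripts use a few hundred peptides
per class with a lighter pipeline configuration (coarser weight grid,
larger RFE step) so they run in seconds.

## Known limitations

* The propensity surrogate and the synthetic scale tables are stand-ins:
  results that hinge on those specific numbers (as opposed to the block
  structure) should be re-derived with the genuine external tables where
  available. Tests never assert agreement with any external propensity
  program.
* The frozen composite coefficients were fitted on a corpus this package
  does not redistribute; refitting them here on synthetic data will not
  reproduce them.
* ReliefF hyperparameters (k = 10 neighbours, full-sample scoring by
  default, cutoff 0) are package defaults; the outcome of a relevance
  filter is data-dependent by nature.
* The weight grid at resolution 0.1 is exhaustive but coarse; gradient or
  finer search could shave fractions of a percent.
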