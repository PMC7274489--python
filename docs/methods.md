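# Methods

## Problem and model

Proteins function in specific cellular compartments, and many plant
proteins reside in two compartments at once (for example cytoplasm and
nucleus). `plantloc` treats localization prediction as flat multi-class
classification over 14 classes: 11 single compartments (plastid,
cytoplasm, extracellular, nucleus, mitochondrion, cell membrane, Golgi
apparatus, endoplasmic reticulum, vacuole, peroxisome, cell wall) and 3
dual compound classes (mito-plastid, cyto-nucleus, cyto-Golgi). Dual
localization is deliberately modeled as atomic compound classes, not as
thresholded multi-label output; each compound class keeps its mapping to
the underlying pair of single compartments for reporting.

A sequence is mapped to a numeric descriptor vector by one of eight
encoders (or a hyphenated hybrid concatenation), the matrix is z-score
standardized with training-set statistics, and a one-vs-rest (OvR)
ensemble of binary RBF-kernel SVMs is trained — one classifier per
class, that class positive and all others negative. Prediction takes
the class whose binary classifier reports the largest signed decision
value; exact ties break in class-list order for determinism. Decision
values, not calibrated probabilities, are the confidence scores.

## Feature encoders

All composition-type outputs are fractions in [0, 1]; percent is a
display concern only.

- **AAC** (20): residue frequencies, alphabetical one-letter order.
- **DIPEP** (400): overlapping dipeptide counts over N−1 windows,
  row-major over ordered residue pairs.
- **PseAAC** (20+λ): classic type-1 pseudo amino-acid composition. The
  sequence-order factor θ_j averages, over positions, the mean squared
  difference of three per-residue properties (hydrophobicity,
  hydrophilicity, side-chain mass, each standardized to mean 0 and unit
  population variance over the 20 residues) between residues j apart.
  First 20 components f_a/(Σf + w·Σθ), last λ components w·θ_j/(same).
  Defaults λ = 20, w = 0.05 — the canonical choices for this descriptor.
- **NCC** (60): AAC of the first 25 residues, the central remainder and
  the last 25 residues, concatenated N–Center–C. The 25/center/25 split
  is exactly what the package's > 50-residue length filter guarantees to
  be non-degenerate.
- **PHYSCHEM** (26): fractions of residues in 21 fixed, possibly
  overlapping property groups (acidic, basic, charge-neutral,
  hydrophobic/hydrophilic/neutral hydropathy, aromatic, aliphatic,
  polar/nonpolar, tiny/small/large, sulfur-containing, amide, hydroxyl,
  positively/negatively charged, proline, glycine, cysteine) plus the
  fractions of C, H, N, O and S atoms over all residue atoms
  (peptide-chain residue formulas, i.e. amino acid minus one water).
  The exact component list is a design choice of this package; the
  property families it covers are the standard ones for this encoder.
- **CTDC** (21): for each of 7 attributes (hydrophobicity, normalized
  van der Waals volume, polarity, polarizability, charge, secondary
  structure, solvent accessibility) residues are recoded into three
  classes by the standard grouping table and the class fractions n_r/N
  are emitted.
- **CTDT** (21): per attribute, the frequency (n_rs + n_sr)/(N−1) of
  adjacent positions switching between the unordered class pairs
  (1,2), (1,3), (2,3). The symmetric sum is used because a transition
  frequency cannot be negative. Homopolymers give the zero vector.
  Distribution (D) descriptors are intentionally not implemented: no
  model here uses them.
- **QSO** (20+maxlag): τ_d = Σ_i d(R_i, R_{i+d})² over a 20×20
  physicochemical distance matrix; components are residue counts and
  w·τ_d, all divided by N + w·Στ so the full vector sums to 1. Defaults
  maxlag = 30, w = 0.1. The shipped matrix is the Grantham (1974)
  distance — computable in closed form from published composition,
  polarity and volume values — normalized to maximum 1 so lag terms
  stay commensurate with counts. Grantham is one of the two canonical
  matrices for this descriptor family; choosing it keeps the matrix
  fully reproducible from a formula rather than an opaque data blob.

Hybrids concatenate part vectors left to right with part-prefixed
component names; `PseAAC-NCC-DIPEP` (500-d at λ=20) is the
best-performing recipe and the default.

## Input contract

Sequences must use the 20 standard residue letters and be strictly
longer than 50 residues (the NCC split needs a non-empty center; length
exactly 50 fails). Ambiguous residues (B, J, O, U, X, Z, …) cause
rejection by default; a `drop` policy removes them and re-checks the
length. Validation never raises — it partitions input into accepted and
rejected-with-reason. Labels come from a two-column TSV sidecar, or a
`|label=` suffix on the FASTA id token as a fallback.

## Training, hyperparameters and evaluation

The RBF width can be given as gamma directly or as sigma with
gamma = 1/(2σ²), the conventional k(x,y) = exp(−‖x−y‖²/2σ²)
parameterization. Regime defaults for the hybrid encoder: single-label
and combined models σ = 50, C = 500; dual-only C = 10, gamma = 0.001.
No class weighting is applied by default despite class imbalance (a
`--class-weight` switch exists). Standardization uses training-fold
statistics only, so rescaling any raw feature column is absorbed.

Evaluation uses stratified k-fold cross-validation (default k = 5,
seed = 1). Stratification is a deliberate choice: with 30–40-member
classes, unstratified folds can lack a class entirely. A class with
fewer members than k triggers a warning and folds simply lack it; a
class with fewer than 2 training samples in some fold is excluded from
that fold's model and its test samples count as errors. Per-class
statistics are computed from confusion counts pooled over folds
(per-fold accuracies are retained): sensitivity, specificity, accuracy,
precision, rate of false predictions, error rate and the Matthews
correlation coefficient. Any 0/0 case yields 0 and is flagged
degenerate rather than raised, because small classes in 5-fold runs
make empty denominators routine. Andrews curves
(f_x(t) = x₁/√2 + x₂ sin t + x₃ cos t + …) are provided as a
class-structure diagnostic for high-dimensional feature matrices.

## Synthetic benchmark

The generator emulates class-labeled protein corpora without any
download: residues are drawn i.i.d. from per-class weight profiles, and
optional fixed N-/C-terminal motifs overwrite sequence ends. The default
14-class benchmark gives each class a distinct pair of signature
residues boosted 6-fold over baseline, adds 10-residue terminal motifs
to the three dual classes (so terminal-segment and order-sensitive
encoders carry signal), draws lengths uniformly from [80, 250], and uses
an imbalanced plastid-dominant size profile (40–100 per class, ~730
total) with a 10% per-class held-out split — sizes chosen so the full
pipeline trains in seconds on one CPU while preserving the
imbalanced-corpus character of real plant data. A `balanced` override
gives 60 per class.

What the benchmark does *not* emulate: real targeting signals, Markov
or homology structure, shared ancestry between sequences, or realistic
between-class overlap. Sequences are i.i.d. draws with engineered
separability, so near-perfect cross-validation accuracy on it
demonstrates that the pipeline is wired correctly end to end — not that
any particular accuracy would be attained on curated UniProt corpora.

## Numerical choices and limitations

- Encoders are pure functions; identical input gives bit-identical
  output. Composition blocks sum to 1 within 1e-9.
- Fold assignment, residue sampling and SVM seeding all derive from
  explicit integer seeds; repeated runs reproduce reports exactly.
- Degenerate metric denominators return 0 with a flag (see above).
- Serialized models are joblib archives carrying a format version, the
  encoder recipe, class list and standardizer; loading a corrupt or
  version-mismatched file raises a load error rather than crashing.
- Homology-based prediction, GO/PSSM features, UniProt retrieval and
  redundancy reduction are out of scope; users supply pre-built FASTA
  corpora.
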