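# Methods

## Scope and overall procedure

`zfpwm` predicts the DNA-binding specificity of Cys2His2 zinc-finger
(C2H2-ZF) proteins as position weight matrices (PWMs), from sequence alone.
The pipeline has five stages: (1) detect C2H2-ZF domains and their
recognition helices; (2) group consecutive domains into DNA-binding arrays
by linker length; (3) score every finger against all 256 possible 4-bp
subsites with an empirical contact-energy model; (4) convert scores to
per-position nucleotide probabilities through a Boltzmann distribution and
merge per-finger PWMs across the shared junction base; (5) optionally,
align predictions to experimental PWMs and assess significance against a
column-randomized null.

## Domain detection

The detector is a regular-expression matcher with the default pattern
`C-x(1,5)-C-x(10,14)-H-x(3,6)-H`, scanned left to right without overlap;
lazy quantifiers anchor each zinc-coordinating residue at its most
N-terminal legal position. An optional `allow_cchc` flag accepts a
terminal Cys (CCHC variants); it is off by default. Helix residues are
anchored on the first coordinating histidine at domain index `h`:
positions −1..6 occupy `h−7 .. h−1` (the Zif268 convention), so the four
specificity residues sit at `h−7, h−5, h−4, h−1`. Externally computed
domain coordinates can be imported from a tab-delimited table
(`protein_id  start  end`, 0-based half-open) when parity with an HMM-based
scan is required; atypical fingers are the main place where the regex and a
profile HMM can disagree.

Fingers whose last-His-to-next-first-Cys gap is at most `max_linker = 12`
residues share an array; longer gaps split arrays. Canonical arrays have
9–12 residue linkers; 12 is the inclusive default bound. Single-finger
arrays are constructed and predictable (a 4-column PWM) but most uses
concern arrays of two or more fingers.

## Interface encoding and scoring

An interface between a finger and a 4-bp subsite is a sparse indicator
vector with one active entry per contact: `x[a, b, c] = 1` when amino acid
`a` meets base `b` at contact `c`. The canonical model has four contacts
(a6b1, a3b2, a−1b3, a2b4; 4×4×20 = 320 dims), the expanded model seven
(adding a2b3, a−1b4, a6b2; 560 dims). The index layout is contact-major
(`idx = c*80 + b*20 + a`, bases A,C,G,T, amino acids alphabetical) and is
recorded verbatim in every saved weight file so externally trained vectors
remain portable. An unknown residue `X` simply activates nothing for its
contacts — zero energy — so whole-proteome scans never abort.

Scoring models are soft-margin max-margin fits with hinge loss and **no
intercept** (the score of an empty interface is exactly zero), trained with
liblinear (scikit-learn's `LinearSVC`). For a linear model the `abc`-th
weight is the empirical contact energy of (a, b, c) and the score is
`w·x`. The degree-2 polynomial variant uses the homogeneous kernel
`K(x, z) = (x·z)²`, realised exactly through its explicit quadratic
feature map (diagonal terms weight 1, unordered cross terms √2); this is
the same hypothesis class as a no-intercept kernel SVM and keeps the
origin constraint by construction, at the price of storing the
quadratic-space weight vector instead of support vectors. `regularization="auto"`
maps to the classic heuristic `C = 1/mean(||x||²)` (0.25 for the canonical
encoding, 1/7 for the expanded). Training is deterministic for a fixed
example order (fixed liblinear seed). Any callable `(finger, site) -> float`
is accepted wherever a `ScoringModel` is, as a custom scoring hook.

## From scores to PWMs

The 256 subsites are treated as the states of a statistical-mechanical
system. With the score `y_i` negatively proportional to the binding energy
of state `i`,

    P_i = bg(i) · exp(λ·y_i) / Z,

where `λ` (default **4**) converts scores into units of kT, `bg(i)` is the
product of background base probabilities over the site (uniform by
default; any probability 4-vector may be supplied for biased genomes) and
`Z` normalizes. Boltzmann weights are computed after subtracting the
maximum exponent, so arbitrarily large scores cannot overflow. The PWM
column at position `pos` is the marginal `p(b | pos) = Σ_i P_i δ_i(b, pos)`.
Because every contact touches exactly one base position, linear scores are
additive over positions and the marginals factorize; the linear path
computes each column directly from the (4 positions × 4 bases) energy
table, and is exactly equivalent to the 256-state enumeration (asserted to
1e-9 in the tests). Polynomial and custom scorers always use the full
enumeration. `λ` chiefly controls the information content of the
prediction: it multiplies the score scale, so it is kept exposed rather
than hard-wired — a scorer trained on different data has a different
natural score spread.

Adjacent fingers bind overlapping subsites: the junction base is contacted
by residue a6 of the N-adjacent finger (its b1 contact) and residue a2 of
the following finger (its b4 contact). The junction column is

    p_b ∝ (p_prev,b)^α · (p_next,b)^(1−α),     α = 0.75 by default,

where `p_prev` is the N-adjacent finger's b1 column. `α = 1` and `α = 0`
return one finger's column exactly (implemented as literal pass-through,
not a powered copy); `α = 0.5` is the normalized geometric mean. The 0.75
default reflects the closer approach of a6 to the primary strand. If the
two columns share no support (renormalization mass < 1e-12), a uniform
column is emitted, a `DegenerateJunctionWarning` is raised, and the column
index is recorded in the output PWM's `degenerate_columns`. Fingers map
onto the site antiparallel to the primary strand — the C-terminal finger's
subsite is 5′-most — so an n-finger array yields 3n+1 columns.

## PWM I/O conventions

Nucleotide order is fixed as A,C,G,T everywhere. Matrices are read from
JASPAR, TRANSFAC and MEME-minimal dialects (via Bio.motifs) and a plain
4-row TSV; every column is normalized by its sum on read, which transparently
converts count matrices, and a zero-sum column is an error. No pseudocounts
are added at any point: information content uses the `0·log₂0 = 0`
convention, so exact zeros are legal throughout. Column IC is
`2 + Σ_b p_b log₂ p_b ∈ [0, 2]` bits. Trimming removes columns with
IC < 0.5 from the 5′ and 3′ ends only; interior low-IC columns are kept,
and an empty result is legal (such matrices are excluded from alignment
with a warning). The reverse complement of a stored matrix is the
anti-diagonal flip (reverse both axes).

## Alignment and significance

Columns are compared with the IC-weighted Pearson correlation
`PCC(pred, exp) · IC(exp)/2`. A uniform column has undefined PCC; it is
defined as 0 (no preference). The score is bounded by `IC(exp)/2`, so an
experimental column with IC < 0.5 can never reach the 0.25 threshold used
to call a column correctly predicted — the per-column accuracy measure is
deliberately conservative about uninformative columns.

Matrix alignment is ungapped and local: over both orientations of the
experimental matrix, all offsets, and all contiguous windows of at least
`min_overlap` columns (default 3 — one subsite minus the junction — to
suppress spurious single-column maxima; configurable), the window with the
largest summed column score wins. Ties are broken toward the *shorter*
span, then the forward orientation, then the smaller offset and window
start: zero-scoring columns (e.g. uniform flanks) are therefore excluded
from the reported span rather than absorbed into it. The search is
asserted equal to literal enumeration of all candidates in the tests.

The empirical p-value compares the observed total score with `n_random`
(default 10 000) matrices of the experimental matrix's width, assembled by
sampling columns uniformly with replacement from a background pool —
in practice, columns taken from a motif database matched to the organism.
The estimator is `(1 + #{null ≥ observed}) / (n_random + 1)`: never zero,
conservative on ties. A protein-level prediction is called correct when
the minimum p-value over all (array, trimmed experimental PWM) pairs is at
most 0.05; no multiplicity correction is applied, mirroring the
at-least-one-match criterion. Null alignments are evaluated in a batched,
vectorized form of the same window search; tie-breaks are irrelevant there
because only the maximum total enters the p-value.

## Synthetic data: what it emulates and what it does not

The generators exist so that every pipeline stage is testable without
external downloads.

* **Planted training sets.** A ground-truth weight vector w* is drawn
  i.i.d. Gaussian over the encoding and standardized to unit score-SD
  (below). Random (helix, site) pairs — helices uniform over the 20 amino
  acids, sites uniform over ACGT unless a C/G composition bias is requested
  — are labelled `+1` when `w*·x ≥ margin` and `−1` when `w*·x ≤ −margin`
  (default margin 0.1 score-SD; dead-zone pairs are resampled, with a 10⁶
  draw cap). Class counts are exact; the natural scale mirroring
  literature-derived collections is 1312 positives / 8081 negatives.
* **"Experimental" PWMs.** Each true-motif column is resampled from a
  Dirichlet centred on it (concentration 50 by default — visibly noisy but
  clearly the same motif); `n_flank` near-uniform columns
  (Dirichlet(7.5,7.5,7.5,7.5), IC almost always < 0.5) are appended on each
  side, emulating the uninformative ends of database motifs; the matrix is
  reverse-complemented with a configurable probability.
* **Background pools.** Columns are Dirichlet(α,α,α,α) draws; at α = 1 the
  mean IC is 2 − (ψ(5) − ψ(2))/ln 2 ≈ 0.44 bits, a mix of informative and
  flat columns comparable to database column pools. Mean IC decreases
  monotonically in α.

Two conventions deserve note. First, **scale standardization**: binary
bind/no-bind labels identify only the direction of the weight vector, not
its length, while the Boltzmann conversion at fixed λ is scale-sensitive.
Planted and recovered scorers are therefore both rescaled to unit score
standard deviation over a fixed calibration sample (the scenario's 50
calibration fingers × all 256 sites) before PWMs are compared. Second, the
**recovery scenario trains the canonical model with a hard margin
(C = 100)**: the planted labels are noiseless and separable by
construction, so a hard margin is the appropriate estimator, and the
4-contact encoding keeps the example-to-dimension ratio (4000 : 320)
comfortable.

Passing these tests shows that the machinery — encoding, optimization,
Boltzmann conversion, merging, alignment, calibration of the null — is
internally correct and recovers planted truth. It does *not* show that
predictions match real proteins: natural helices are far from uniform over
amino acids, real binding has dependencies beyond pairwise contacts and a
single junction base, experimental motifs are not Dirichlet-perturbed
truths, and a scorer is only as good as its training interfaces.
Sequence-level constructs additionally restrict helices to non-C/H
residues so the planted domain boundaries are unambiguous.

## Numerical choices and degenerate inputs

* PWM columns are validated to sum to 1 within 1e-9; readers normalize.
* Boltzmann exponents are max-shifted before exponentiation.
* Zero-variance columns in PCC → 0; zero-support junctions → uniform plus
  a warning and a recorded column index.
* Alignment tie-breaks are exact lexicographic comparisons on
  (total, −span, forward, −offset, −start).
* p-value comparisons use `null ≥ observed − 1e-12` (conservative).
* Model files store only nonzero weights at full float precision (`%.17g`),
  so save/load round-trips scores to 1e-12.
* Problem sizes in the test suite (e.g. 200 calibration replicates at
  n_random = 999; 50 recovery replicates at 2000+2000 training pairs) were
  chosen as the smallest sizes at which the asserted bounds are stable
  estimates.

## Known limitations

* Domain detection is a regex, not a profile HMM; unusual spacer lengths
  or degenerate fingers can be missed (use the domain-table import for
  parity with an external scan).
* Which arrays of a multi-array protein actually bind DNA is not
  predicted; all arrays are reported.
* Inter-finger dependencies beyond the single shared junction base are not
  modeled, and the polynomial kernel captures within-finger contact
  interactions only.
* Only the IC-weighted PCC column measure is implemented; the alignment
  code accepts alternative column scorers internally but none are exposed.
* No pre-trained weights are bundled; users supply training examples or a
  weight file in the documented layout.
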