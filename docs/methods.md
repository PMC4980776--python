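# Methods

## Signature descriptor

An atom signature at height h encodes the ball of radius h around a root
atom: every atom within h bonds and every bond among them. The text
grammar is bracketed atom labels (element symbol, lower-cased when
aromatic, optional charge suffix: `[C]`, `[c]`, `[O-]`), children rendered
inside one pair of parentheses per vertex, each child prefixed by its bond
symbol (`""` single, `=` double, `#` triple; aromatic bonds implied by the
aromatic labels). Rings make the breadth-first expansion re-visit atoms:
an atom reached along several branches is rendered in each branch, a bond
between two atoms of the same BFS layer is rendered as a leaf
back-reference inside that layer, and every atom occurring more than once
carries a closure integer shared by all its occurrences (numbered by first
appearance). Same-layer ring bonds are deliberately encoded *within* their
layer rather than by expanding one layer further: this keeps the
saturation property exact — the text stops changing at precisely the
root's eccentricity (cyclopropane, eccentricity 1, already closes its ring
at h = 1).

Canonical order: children are sorted by their fully rendered subtrees with
closure digits blanked; residual ties, which can only change the output
when closures are involved, are resolved by taking the lexicographically
smallest complete string over the tied orderings (the search is capped at
10,000 combinations — far beyond anything drug-like molecules at heights
≤ 4 produce; the cap exists for adversarially symmetric ring lattices).
The encoding is constitution-only: stereochemistry is ignored.

Tests enforce the properties that matter — invariance under atom
relabelling, identical texts within automorphism orbits (checked against
brute-force isomorphism enumeration), saturation at the eccentricity —
rather than a byte-level dialect, since any deterministic order-invariant
grammar is equally valid.

**Height pooling.** Molecule featurization pools heights 1–3 by default.
Per root atom, identical texts arising at different heights (a small
molecule saturating early) are counted once; across roots, counts
accumulate. This avoids double counting for molecules smaller than the
largest height.

## Data handling

Property tables are CSV/TSV with a SMILES column and a value column;
qualifiers may sit in their own column (`<`, `<=`, `=`, `>=`, `>`) or as a
prefix on the value string — both dialects map to the same enum. Records
with an inequality qualifier are dropped (a "greater than cutoff" entry
has no usable regression target); the optional log transform is log₁₀,
the convention for solubility- and logD-type endpoints. Duplicate
structures are kept as separate records; no standardization (salt
stripping, tautomer canonicalization) is attempted.

## Solver

The linear SVR minimizes ½‖w‖² + C Σ max(|w·x − y| − ε, 0)² via its dual:
f(β) = ½βᵀQβ − yᵀβ + ε‖β‖₁ + ‖β‖²/(4C), minimized coordinate-wise with
exact soft-thresholded Newton steps, coordinates visited in a freshly
randomized order per sweep (numba-compiled inner loop; deterministic per
seed). Termination: largest projected-gradient violation in a sweep ≤
tolerance (default 1e-5) or the sweep budget (default 2000). A debug mode
asserts the dual objective never increases between sweeps. With ε = 0 the
problem is exactly ridge regression with penalty 1/(2C), which the tests
exploit as a closed-form oracle (agreement to ~1e-13 on small dense
problems at tolerance 1e-12).

Defaults: ε = 0.1 (a prediction-oriented tube width of the order of
measurement noise on log-scale endpoints), bias fitted as an appended,
regularized constant feature (disable with `fit_bias=False`).

Cost selection: k-fold CV (default k = 5) with one fold partition shared
across the grid; mean fold RMSDs within 1e-6 relative are treated as equal
performance and the lowest such cost wins — the optimistic, least-complex
choice. Default grid: 0.005, 0.05, 0.1, 0.5, 1, 10, 100.

No kernel solver is implemented in-repo: RBF training enters through a
backend contract (train(matrix, labels, params) → predictor), fulfilled by
a scikit-learn SVR adapter and checked by a shared compliance suite.

## Experiment harnesses

*Learning curve*: a test set (20% of the data, capped at 50,000) is drawn
once per seed; for each (size, replicate) an independent training
subsample is drawn without replacement from the remainder, the signature
dictionary is rebuilt from that subsample (as a real training run would),
and test RMSD is recorded; three replicates per size by default,
summarized by per-size medians. Test data never enter any training
subsample. *Grid search*: every (cost, γ) cell evaluated on one fixed
split; argmin ties break toward lower cost, then lower γ, making the
result independent of grid enumeration order. Build times are recorded as
information only — they depend on hardware and are never asserted.

## Interpretation

Each surviving (root, text) signature occurrence credits its full weight
to its root atom, so Σ per-atom raw scores + bias equals the prediction
exactly (conservation is asserted to 1e-10 in tests). The alternative —
smearing a signature's weight over its subtree — was rejected because it
has no canonical split and breaks exactness. Normalized scores are
raw / max|raw| in [−1, 1] (all zero when every raw score is zero); the
endpoints of the colour scale are thus molecule-relative, a documented
choice. The top signature is the occurrence with maximal |weight| (ties:
lower atom index, then shorter text); its "coloured atom set" is the
height-h ball around its root.

## Synthetic data

The generator emulates the *shape* of a solubility/logD modelling problem,
not its physics: random connected heavy-atom graphs (random spanning tree
plus an optional ring-closing edge, valence-legal single/double bonds,
C/O/N alphabet with probabilities 0.8/0.15/0.05, 4–18 atoms), and a
property y = β·counts + b + N(0, σ²) with sparse β over signature counts.
Defaults — 2000 molecules, σ = 0.1 log units, 10% coefficient sparsity —
are the standard conditions used across the tests. Passing tests therefore
demonstrate correctness of the pipeline and estimator on
linear-in-substructure signals; they do not certify accuracy on real
assay data, whose noise is neither Gaussian nor homoscedastic and whose
structure–property relation is not exactly linear in counts.

Two identifiability choices deserve emphasis. Pooled-height signature
count matrices are exactly rank-deficient by construction: a height-1
count is the sum of its height-2 refinements, bond counts can be tallied
from either endpoint, and rare substructures co-occur within single
molecules. Individual coefficients on such a dictionary are not estimable
by any method. The generator therefore (i) defines the ground truth on
height-1 counts and places its non-zeros on features present in ≥ 5% of
the molecules, and (ii) the recovery experiment prunes features below 3%
training prevalence before fitting — the standard rare-feature cut, which
empirically renders the remaining design full-rank while the 2-point
prevalence margin keeps true-signal features from ever being pruned by
sampling noise. Weights of pruned features stay at zero, which is also
their true value. Recovery fits use ε = 0 (the ridge limit): recovery is
an estimation problem, and a tube of width σ would deliberately ignore
exactly the residuals that identify the coefficients.

Problem sizes in the test suite and acceptance script (2000-molecule
recovery runs, a 100–2000 learning-curve ladder, 400/1000 grid-search
splits) are chosen so the full suite runs in a few minutes on one core
while every statistical claim still has comfortable margin; the harnesses
accept larger sizes unchanged.

## Known limitations

- Signature strings use this package's grammar; other implementations of
  the same descriptor produce different byte-level dialects (equal in
  expressive content for acyclic molecules, by construction of the shared
  parenthesized style).
- Multi-fragment SMILES (salts) are not standardized; each fragment's
  atoms are simply described as-is.
- The canonicalization tie search is capped; pathological highly symmetric
  ring lattices beyond the cap could in principle receive
  non-order-invariant texts (no molecule in scope approaches the cap).
- The linear model's interpretability guarantee (exact conservation) does
  not extend to kernel backends, which are intentionally excluded from the
  attribution path.
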