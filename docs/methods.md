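# Methods

## The model

`slbind` estimates the standard binding free energy of a protein–protein
complex, ΔG⁰_bind (kcal/mol), from a fixed-length vector of interface
descriptors, and reports the corresponding dissociation constant through
ΔG⁰ = RT ln K_D (R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K).

The estimator is a *super learner*: a stacked-generalization ensemble of
ten base regression algorithms (AdaBoost, bagging, decision tree, elastic
net, extra trees, k-NN, linear regression, random forest, SVR, XGBoost)
combined by a meta-model m(z; β) that is linear in the base-learner
outputs z with non-negative weights β. Training proceeds in three steps:

1. **Out-of-fold matrix.** The training set is split into K = 10 folds
   (seeded shuffle, contiguous blocks, sizes differing by at most one).
   For every fold and every learner, the learner is trained on the other
   folds and predicts the held-out fold, giving an n×m matrix Z in which
   no entry was produced by a model that saw its own row. This is the
   construction that keeps the combination step honest: any apparent
   skill in Z reflects generalization, not memorization.
2. **Meta-weights.** β solves min‖Zβ − y‖₂ subject to β ≥ 0, by the
   Lawson–Hanson active-set algorithm implemented in `slbind.nnls`.
   There is no intercept and the weights are not rescaled (a sum-to-one
   renormalization is available as a comparison option). The
   non-negativity constraint drives unhelpful or anti-correlated
   learners to exactly zero weight instead of letting large positive and
   negative coefficients cancel.
3. **Refit.** Every base learner is refitted on the full training set;
   a prediction is ŷ(x) = Σⱼ βⱼ fⱼ(x).

Per-learner out-of-fold RMSE and R² are recorded during step 1 and
reported alongside β; the model combination itself uses only the NNLS
fit. The super learner's own cross-validated metrics (`sl_cv_rmse_`,
`sl_cv_r2_`) are computed by refitting β on the out-of-fold rows of Z
outside each fold and scoring the held-out rows, so they are
cross-validated at both the base and the meta level.

### Hyperparameters

| parameter | default | notes |
|---|---|---|
| K (folds) | 10 | out-of-fold scheme; n ≥ 2K enforced |
| elastic net max iterations | 1,000,000 | convergence at tight tolerance |
| bagging / RF / extra-trees estimators | 1,000 | production ensemble size |
| XGBoost objective | squared error | regression target |
| all other learner settings | library defaults | scikit-learn 1.9 / xgboost 3.0 |
| meta intercept | none | plain NNLS combination |
| master seed | 0 | fold and per-learner seeds derive from it by fixed offsets |

Scale-sensitive learners (elastic net, k-NN, SVR) standardize features
inside their own pipeline, fitted on training folds only, so no
information crosses fold boundaries through the scaler.

## Structure preprocessing

Inputs are PDB files plus two partner chain-ID sets. Rules, in order:

- **Gaps.** Between consecutive protein residues of a chain, a gap is
  flagged when residue numbering jumps by more than one, or when the
  C(i)–N(i+1) distance exceeds 2.5 Å (peptide bond ≈ 1.33 Å; the margin
  absorbs refinement noise). A residue missing any of N/CA/C is flagged
  as "missing heavy atoms". Strict mode rejects gapped structures;
  otherwise gaps are reported.
- **Structural ions.** Single-atom HETATMs of Mg, Ca, Na, Cl, Fe, K or
  Zn are retained iff their distance to the nearest protein atom is
  strictly below 2.0 Å (hydrogens included when present; the atom set is
  configurable). An ion at exactly 2.0 Å is removed.
- **Other heteroatoms.** Waters, small ligands, cofactors, glycan
  residues and non-structural ions are removed and counted by category.
- **Chains** are renamed A, B, C, … in order of first appearance; the
  map is always reported.
- **Resolution** worse than 2.5 Å only warns at prediction time
  (training-set curation treats it as a hard filter); blocking
  predictions on lower-resolution inputs would silently narrow the
  tool's applicability.
- Alternate locations keep the highest-occupancy conformer (first in
  file on ties); only the first MODEL of multi-model files is used;
  hydrogen *placement* is the descriptor engine's job — the module only
  records presence.

## Descriptors

Descriptor computation is a provider contract. The production provider
wraps an external macromolecular-modelling engine (geometry optimization
followed by interface metrics); it raises an explicit capability error
when the engine is absent. The packaged 52-name schema follows the
field's naming conventions (`cms`, `ifa_*`, per-term interface energies)
but is a synthetic stand-in shipped as data — replacing the schema file
swaps in a production descriptor list without code changes. The
synthetic provider used in tests derives a deterministic standard-normal
vector from a content hash of the structure.

## Synthetic data: what it does and does not emulate

`slbind.synthetic` generates both test substrates:

- **Structures** are idealized polyalanine chains (5 heavy atoms per
  residue, exact 1.33 Å peptide C–N links, chains laterally separated)
  with ions planted at *exactly* specified minimum distances and
  waters/ligands/sugars planted away from the ion anchors, so every
  preprocessing assertion is exact counting, no tolerances. They are not
  physically realistic interfaces and carry no binding signal.
- **Tables** follow y = μ + w·x_active (+ optional quadratic or
  interaction term) + ε with standard-normal features, defaults
  μ = −10 kcal/mol, sd(y) ≈ 2.5 kcal/mol, noise σ = 1 kcal/mol and six
  active features out of 52. The label distribution mimics the roughly
  Gaussian spread of experimental affinities over the micromolar-to-
  picomolar window; the features are *not* correlated the way physical
  descriptors are.

Consequently, passing tests demonstrate the statistical machinery —
leakage-free stacking, NNLS optimality, dominance of the combination,
exact preprocessing — not predictive accuracy on experimental
complexes, which depends on the external descriptor engine and curated
affinity data.

## Simulation study configuration

The distribution-level test studies run at n = 500 (pure-noise leakage
check, 5 seeds), n = 300 (dominance study, linear and additive-nonlinear
designs, 5 seeds), and K = 10. For these studies the ten learners run
with 100-tree ensembles for bagging/RF/extra-trees; the stacking
properties under test do not depend on ensemble size, and the package's
production default (1,000) is unchanged and exercised by the acceptance
script's headline fit. The no-skill threshold for the leakage check is
cross-validated R² ≤ 0.05; the dominance margin is 0.05·sd(y).

## Numerical choices

- NNLS stopping tolerance scales as 10·eps·‖A‖₁·max(n, m); KKT
  residuals (stationarity on the support, dual feasibility off it) are
  verified to 1e-8 in tests. Numerically degenerate restricted
  subproblems (vanishing columns) terminate with the best feasible
  iterate.
- The stratified splitter quantile-bins the labels (10 bins by default)
  and apportions per-bin training counts by largest remainder, so the
  overall train share is exactly round(0.8·n); two-moment agreement of
  the subsets is tested over seeds.
- An all-zero β (no learner helps) warns rather than fails; predictions
  are then 0 and flagged.
- R² of a zero-variance target is reported as 0.0 (undefined); the
  Pearson correlation raises a structured error instead.
- The Shapley explainer is the permutation-sampling estimator with
  background imputation; background rows are cycled in shuffled order
  (stratified) rather than drawn i.i.d., removing the background-mean
  variance component. Local accuracy holds up to Monte Carlo error.
  Ties in the importance ranking break by schema order.

## Known limitations

- Descriptor energetics are not reproduced in-repo; without the
  external engine the pipeline runs only with synthetic descriptors.
- mmCIF input, hydrogen placement, rotamer/flip sampling and
  temperature-dependent ΔH/ΔS decomposition are out of scope.
- Chain renaming is limited to 26 single-letter IDs.
- Metric confidence intervals are not computed.
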