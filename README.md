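# slbind

Structure-based prediction of absolute protein–protein binding free
energies with a super-learner ensemble.

## The problem

The strength of a protein–protein interaction is summarized by its
standard binding free energy ΔG⁰_bind (kcal/mol), related to the
dissociation constant by

    ΔG⁰ = RT ln K_D        (R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K)

so a nanomolar binder corresponds to about −12.3 kcal/mol. Measuring
K_D is slow and expensive; estimating ΔG⁰ directly from a complex's
3-D structure makes it possible to triage thousands of designed or
modelled interfaces — antibody candidates, docking decoys, protein
designs — before any experiment. `slbind` is for computational
structural biologists who have protein–protein complex structures (PDB
files) and want fast, reproducible affinity estimates plus an account
of which interface properties drive them.

## The method

Each complex is reduced to a 52-component vector **z** of interface
descriptors (contact molecular surface, interface-analyzer metrics,
per-term interface energies). A *super learner* maps **z** to ΔG⁰:
m base regression algorithms f₁…f_m (ten by default: AdaBoost, bagging,
decision tree, elastic net, extra trees, k-NN, linear regression,
random forest, SVR, XGBoost) are combined by a meta-model

    m(z; β) = Σⱼ βⱼ fⱼ(z),    β ≥ 0,

whose weights solve the non-negative least-squares problem
min‖Zβ − y‖₂ (Lawson–Hanson active set). Crucially, Z is the matrix of
*out-of-fold* predictions from a shared 10-fold scheme — each entry
comes from a model that never saw that sample — so the weights reward
generalization, not memorization. The base learners are then refitted
on the full training set and predictions are their β-weighted sum. A
permutation-sampling Shapley explainer attributes each prediction to
the descriptors (in kcal/mol).

Pipeline: PDB in → QC (backbone-gap search; structural ions Mg/Ca/Na/
Cl/Fe/K/Zn kept iff < 2.0 Å from a protein atom; all other heteroatoms
removed; chains renamed A, B, C…) → descriptor provider → super-learner
prediction → ΔG⁰ and K_D. Descriptor computation is a provider
contract: the production provider wraps an external modelling engine,
and a deterministic synthetic provider makes the whole pipeline
testable without it. See `docs/methods.md` for the full model
description.

## Worked example

Generate a synthetic labeled descriptor table and a synthetic two-chain
complex (no downloads needed), train, and predict:

```python
from slbind.synthetic import (SyntheticTableSpec, SyntheticStructureSpec,
                              make_table, make_pdb)
from slbind.descriptors import write_table

table, truth = make_table(SyntheticTableSpec(n=100, seed=42))
write_table(table, "descriptors.tsv")
make_pdb(SyntheticStructureSpec(ions=(("ZN", 1.9),), n_waters=3), "complex.pdb")
```

```console
$ slbind train --table descriptors.tsv --k 5 --seed 0 --out model --tree-estimators 100
model	cv_rmse_kcal_mol	cv_r2	weight
adaptive_boosting	1.6308	0.5134	0.285072
bootstrap_aggregation	1.6416	0.5070	0.110840
decision_tree	2.4391	-0.0885	0.000000
elastic_net	1.6751	0.4866	0.146352
extremely_randomized_trees	1.5733	0.5471	0.035102
k_nearest_neighbors	2.2215	0.0970	0.000000
linear_regression	1.7276	0.4539	0.431180
random_forest	1.6083	0.5268	0.000000
support_vector_regression	2.0926	0.1988	0.000000
extreme_gradient_boosting	1.7919	0.4125	0.000000
super_learner	1.5159	0.5796	1.008546
```

Each base-learner row shows its 5-fold out-of-fold RMSE (kcal/mol) and
R² on this 100-complex table, and the NNLS meta-weight it earned: here
the combination leans on linear regression, AdaBoost and elastic net,
zeroes out five learners, and its own cross-validated RMSE
(1.52 kcal/mol) beats the best single learner (1.57). `--tree-estimators
100` shrinks the bagging/forest ensembles for a quick demo; the
production default is 1000.

```console
$ slbind predict --ipdb complex.pdb --partner1 A --partner2 B --model model
id	dg_kcal_mol	kd_molar	n_gaps	n_structural_ions	n_removed_het	resolution_pass
complex	-8.7889	3.611429e-07	0	1	3	True
```

The complex is predicted to bind at −8.79 kcal/mol, i.e. K_D ≈ 0.36 µM
(the two numbers are exact thermodynamic transforms of each other); QC
found no backbone gaps, kept the planted zinc as a structural ion, and
removed the three waters. Add `--print-individual` for the ten
per-learner predictions, `--strict-gaps` to reject gapped structures.

```console
$ slbind evaluate --table descriptors.tsv --model model --split-seed 0
model	rmse_kcal_mol	pearson_r	n
super_learner	0.7774	0.9853	20
```

(Here the model was trained on the full demo table, so this split
evaluation is optimistic; `slbind evaluate` is meant for bundles
trained elsewhere.)

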