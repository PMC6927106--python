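"""Hierarchy-aware cross-validation with the eight ranking criteria.

Known annotations are split into 5 folds; for each held-out pair (p, h),
every training annotation of p to a descendant of h is also removed, so the
model cannot read the answer off the ontology closure.  One fold is
evaluated here with the full eight-criterion report: pooled (annotation-
centric) AUC/AUPR, per-protein and per-term averages, leaf-term averages,
and the five annotation-count bins.
"""

from hpofactor import evaluation, factorization, pipelines, synthetic

scenario = synthetic.SyntheticScenario(
    n_proteins=150, n_terms=100, true_rank=6, seed=3
)
data = synthetic.generate_scenario(scenario)
Y, dag = data["Y"], data["dag"]

plan = evaluation.make_cv_splits(Y, dag, Y.col_index, repeats=1, folds=5, seed=3)
fold = plan.repeats[0][0]
print(f"fold: {len(fold.test_pairs)} test pairs, "
      f"{len(fold.removed_pairs)} descendant pairs additionally hidden")

W = fold.train_mask(Y.values)
Sh = pipelines.nhpo_from_matrix(Y, dag, train_mask=W)
hyper = pipelines.default_hyperparams(K=scenario.true_rank, seed=3)
model = factorization.fit(Y, W, Sh, data["ppns"], hyper)

test_pos, exclude = fold.matrices(Y.values)
train_counts = ((Y.values == 1) & (W == 1)).sum(axis=0)
report = evaluation.evaluate_predictions(
    factorization.predict(model), test_pos, exclude,
    train_counts, Y.col_index, dag,
)

print(f"AUC        {report.auc:.4f}   AUPR        {report.aupr:.4f}")
print(f"micro-AUC  {report.micro_auc:.4f}   micro-AUPR  {report.micro_aupr:.4f}"
      "   (per-protein averages)")
print(f"macro-AUC  {report.macro_auc:.4f}   macro-AUPR  {report.macro_aupr:.4f}"
      "   (per-term averages)")
print(f"leaf-AUC   {report.leaf_auc:.4f}   leaf-AUPR   {report.leaf_aupr:.4f}")
for label, vals in report.group_macro.items():
    print(f"  terms with {label} training annotations: "
          f"macro-AUC {vals['macro_auc']:.3f} over {vals['n_terms']} terms")
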