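"""Stratified 5-fold evaluation of a full CSP + classifier pipeline.

The feature extractor is refit on each training split (no leakage), the
report aggregates a pooled confusion matrix, and kappa uses the
balanced-class chance level 1/k.  Also shows the pairwise decomposition
of a 4-class problem into 6 binary tasks.
"""

from matrixmi import SyntheticSpec, cross_validate, gen_trials, pairwise_tasks

ts, _ = gen_trials(SyntheticSpec(n_per_class=30, samples=250,
                                 outlier_fraction=0.0, seed=1))
report = cross_validate(ts, {"feature": "csp", "csp_m": 2,
                             "classifier": "svm"}, k=5, seed=0)
print(report.summary())
print(f"\nconfusion matrix (rows true, cols predicted):\n{report.confusion}")
print(f"per-fold accuracies: "
      f"{[round(f['accuracy'], 3) for f in report.fold_results]}")
print("kappa = (accuracy - 1/k) / (1 - 1/k): 0 is chance, 1 is perfect")

pairs = pairwise_tasks(["L", "R", "F", "T"])
print(f"\n4 motor-imagery classes -> {len(pairs)} binary tasks: {pairs}")
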