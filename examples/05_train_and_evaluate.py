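"""Five-fold SVM/KNN evaluation of the two binary MI tasks.

Builds a small three-class synthetic cohort (three subjects per class
with per-subject morphology), extracts EMBD joint features, and runs the
stratified five-fold protocol for the polynomial SVM and KNN. Accuracies
land in the high 90s; the full-size benchmark lives in
scripts/acceptance.py.
"""

from cardiosense.classify import ModelSpec
from cardiosense.experiments import build_synthetic_dataset, tfd_benchmark

dataset = build_synthetic_dataset(n_per_class=90, record_seeds=(1, 2, 3))
print(f"dataset: {dataset.total} traces "
      f"({', '.join(f'{k.value}={v}' for k, v in dataset.class_counts.items())})")

for kind, spec in (("svm_poly3", ModelSpec(kind="svm_poly3")),
                   ("knn", ModelSpec(kind="knn"))):
    results = tfd_benchmark(dataset, tfd_kinds=("embd",), model=spec, seed=0)
    for task, cv in results["embd"].items():
        m, s = cv.mean(), cv.std()
        print(f"{kind:<9} {task:<7} accuracy {m['accuracy']:.3f} "
              f"+- {s['accuracy']:.3f}  recall {m['recall']:.3f}  "
              f"precision {m['precision']:.3f}  F {m['f_score']:.3f}")
print("(task 'stemi' = normal vs ST elevation, 'nstemi' = normal vs "
      "T inversion; metrics averaged over the five folds)")
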