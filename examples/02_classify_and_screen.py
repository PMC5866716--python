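"""Train the classifier roster on one synthetic date and screen it.

Runs a compact scene through feature stacking, sample extraction, a
five-algorithm roster, accuracy assessment and McNemar screening, printing
the per-algorithm overall accuracy and kappa and which algorithms the
screening keeps for the ensemble.
"""

from wetlandchange import (
    ClassifierSpec, SceneConfig, accuracy_report, build_feature_stack,
    build_scene, confusion_matrix, default_signatures, extract_samples,
    pairwise_mcnemar, predict_map, screen_classifiers, train,
)

cfg = SceneConfig(rows=80, cols=80, classes=default_signatures(0.03), seed=7)
scene = build_scene(cfg, n_areas_per_class={c: 12 for c in cfg.proportions()})
stack = build_feature_stack(scene.cube)
samples = extract_samples(stack, scene.reference)
val = samples.subset("validation")

algorithms = ["knn", "mda", "rf", "svmLinear", "pls"]
maps, reports, preds = {}, {}, {}
for alg in algorithms:
    model = train(samples, ClassifierSpec(alg, seed=1))
    maps[alg] = predict_map(model, stack)
    reports[alg] = accuracy_report(confusion_matrix(maps[alg], samples))
    preds[alg] = maps[alg].labels[val.rows, val.cols]

print(f"validation pixels: {len(val)}")
print(f"{'algorithm':<12s} {'OA':>6s} {'kappa':>7s}")
for alg, rep in reports.items():
    print(f"{alg:<12s} {rep.overall_accuracy:6.3f} {rep.kappa:7.3f}")

pvals = pairwise_mcnemar(preds, val.y)
retained = screen_classifiers(reports, pvals, alpha=0.05)
print(f"\nretained for the ensemble (McNemar, alpha=0.05): {retained}")
print("(an algorithm is dropped only when a significantly different "
      "competitor beats its overall accuracy)")
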