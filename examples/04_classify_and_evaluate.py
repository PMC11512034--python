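"""Train both classifier protocols and evaluate them with the metric suite.

Runs the ANN hidden-size sweep (60/20/20 split) and the one-vs-one RBF SVM
(80/20 split) on selected features, then prints confusion matrices and the
per-class accuracy / precision / sensitivity / specificity metrics.
"""

import spicevision as sv

cfg = sv.SimConfig(images_per_level=10, image_size=(96, 96), seed=3)
dataset = sv.generate_dataset(sv.BLACK_PEPPER, sv.SEA_FOAM, cfg)
table = sv.build_feature_table(dataset.images, dataset.labels,
                               levels=dataset.per_sample_levels,
                               crop_keep=0.8)
sel = sv.sfs_select(table, max_features=10, seed=0)
reduced = sv.FeatureTable(features=table.features.iloc[:, sel.selected],
                          labels=table.labels)

# ANN: sweep a few hidden-layer sizes, choose by overall CCR
tr, va, te = sv.split_dataset(reduced, sv.SplitSpec((0.6, 0.2, 0.2), seed=0))
sweep = sv.sweep_structures(tr, va, te, sv.MLPConfig(
    hidden_sizes_to_sweep=(4, 8, 13, 16), max_epochs=200, seed=0))
print(f"ANN sweep chose {sel.n_selected}-{sweep.chosen_hidden_size}-5")

# SVM: one-vs-one Gaussian kernel, C=1000
tr2, _, te2 = sv.split_dataset(reduced, sv.SplitSpec((0.8, 0.0, 0.2), seed=0))
svm = sv.train_svm_ovo(tr2, sv.SVMConfig(C=1000.0))

reports = {}
for method, model, test in (("ANN", sweep.chosen_model, te),
                            ("SVM", svm, te2)):
    m = sv.confusion(reduced.labels, model.predict(reduced), 5)
    rep = sv.metrics(m)
    reports[("black_pepper", method)] = rep
    print(f"\n{method} full-set confusion matrix "
          f"({rep.total - rep.n_errors}/{rep.total} correct):")
    print(m.counts)
    test_ccr = 100.0 * (model.predict(test) == test.labels).mean()
    print(f"{method} held-out test CCR: {test_ccr:.2f}%")

print("\nsummary (macro metrics, %):")
print(sv.report(reports).to_string(index=False))
# accuracy is the macro mean of per-class one-vs-rest accuracy; overall_ccr
# is trace/total — the two "accuracy" conventions in common use.
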