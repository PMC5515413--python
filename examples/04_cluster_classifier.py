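"""Train the neural network that routes proteins to their band.

A single hidden layer of 24 logistic units maps the seven cellular
properties to P(C1), P(C2), P(C3); empirical cluster priors reweight the
output. The hidden-layer width can also be chosen by cross-validation.
"""

from halflife_xfer import (ClassifierSpec, assign_clusters, classify,
                           fit_global_regression, generate, liverlike_preset,
                           select_hidden_units, train_classifier)

dataset, _ = generate(liverlike_preset(seed=1))
fit = fit_global_regression(dataset)
asn = assign_clusters(dataset, fit)

clf = train_classifier(dataset, asn, ClassifierSpec(hidden_units=24, seed=0))
print(f"training accuracy with 24 hidden units: "
      f"{clf.training_accuracy:.1%} on {len(asn.labels)} common proteins")
print(f"class priors (C1, C2, C3): "
      + ", ".join(f"{p:.3f}" for p in clf.class_priors))

rec = dataset.records[0]
label, proba = classify(rec, clf)
print(f"protein {rec.protein_id}: routed to {label}, "
      f"P = ({proba[0]:.2f}, {proba[1]:.2f}, {proba[2]:.2f}), "
      f"true band {asn.labels[rec.protein_id]}")

best, accs = select_hidden_units(dataset, asn, candidate_counts=(8, 16, 24))
print("cross-validated accuracy by hidden-unit count: "
      + ", ".join(f"{h}: {a:.2f}" for h, a in accs.items()))
print(f"-> selected {best} hidden units; routing unseen proteins to a band")
print("   decides which per-cluster linear model predicts their half-life.")
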