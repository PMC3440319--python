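"""SVM-RFE signature discovery with the one-SE parsimony rule.

A linear SVM is trained on all pooled samples; genes with the smallest
squared weights are eliminated round by round while repeated five-fold CV
tracks each round's accuracy.  The reported signature is the smallest round
within one standard error of the best accuracy, and per-gene weights are
selection frequencies over stratified bootstrap reruns.
"""

import warnings

import sarcsig

warnings.simplefilter("ignore")

matrix, phenotypes, truth = sarcsig.simulate_expression_cohort(
    sarcsig.ExpressionSimConfig(n_genes=500, seed=1)
)
samples = phenotypes.select_samples(classes=["US", "CS", "HC"])
y = phenotypes.binary_labels(samples, ["US", "CS"], ["HC"])
sub = matrix.subset_samples(samples)

trace = sarcsig.rfe(sub, y, sarcsig.RFEConfig(seed=3, cv_repeats_per_round=5))
summary = trace.summary()
print("accuracy along the elimination path (every 10th round):")
print(summary.iloc[::10].to_string(index=False))

signature = sarcsig.select_parsimonious_signature(trace, sub, y)
print(
    f"\nparsimonious signature: {signature.size} genes: "
    + ", ".join(signature.genes)
)

weights = sarcsig.selection_frequency_weights(
    sub, y, target_size=signature.size, n_resamples=50, seed=4
)
print("\nselection-frequency weights (fraction of bootstrap reruns")
print("in which the gene survived to the final signature size):")
print(weights.head(10).round(2).to_string())
overlap = len(set(signature.genes) & set(truth.signature_genes))
print(f"\n{overlap}/{signature.size} selected genes are planted signature genes.")
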