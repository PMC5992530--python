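"""Induce a gain-ratio decision tree and read its classification rules.

Builds a J4.8-style tree on the full synthetic dataset (training set =
test set, so the accuracy is resubstitution accuracy and optimistic)
and prints the rule text: each internal line is a test on one
morphological attribute, each leaf shows the taxon with the weighted
number of grains reaching it and the weighted misclassifications.
"""

from pollentree import (
    build_tree,
    default_config,
    evaluate,
    export_rules,
    generate_dataset,
    split_attributes,
)

table = generate_dataset(default_config(seed=42))
tree = build_tree(table)

print(export_rules(tree))
result = evaluate(tree, table)
print(f"resubstitution percent correct: {result.percent_correct:.2f}")
print(f"split attributes: {sorted(split_attributes(tree))}")
print()
print(result.confusion.round(1))

# Fractional weights appear in the leaf annotations whenever a grain
# with missing oncus values was routed down several branches of an
# oncus-width test.
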