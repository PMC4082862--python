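"""Single- and two-marker threshold classification on detection patterns.

Rebuilds the learning- and validation-series presence matrices from the
printed per-group detection counts (ZNF441 in 10/10 then 9/10 regression
samples, never in persistence; PLD6 in 7/10 then 5/10), derives the ROC
threshold, and applies the stump, the CART-style tree and the logistic
ranking.
"""

import numpy as np

from spcregress import (
    SpectralCountMatrix,
    apply_rules,
    fit_two_node_tree,
    logistic_rank,
    roc_threshold,
)


def presence_matrix(znf_reg, pld_reg):
    """Offset counts: detected regression samples 2, everything else 1."""
    samples = [f"r{i}" for i in range(10)] + [f"p{i}" for i in range(10)]
    znf = [2 if i < znf_reg else 1 for i in range(10)] + [1] * 10
    pld = [2 if i < pld_reg else 1 for i in range(10)] + [1] * 10
    return SpectralCountMatrix(
        counts=np.array([znf, pld]), protein_ids=["ZNF441", "PLD6"],
        sample_ids=samples,
        group_of={s: ("regression" if s[0] == "r" else "persistence")
                  for s in samples},
        offset_applied=True,
    )


learning = presence_matrix(10, 7)
validation = presence_matrix(9, 5)

rule = roc_threshold(learning.counts[0], learning.y(), "ZNF441")
print(f"ROC stump: {rule.accession} > {rule.threshold:.1f} predicts "
      f"{'regression' if rule.direction == 'gt_is_regression' else 'persistence'}"
      f"  (equivalent to the <=1 vs >1 detection rule)")

for name, m in (("learning", learning), ("validation", validation)):
    _, s = apply_rules(rule, m)
    print(f"  {name} series: {s['n_correct']}/{s['n_samples']} correct "
          f"({s['correct_by_group']['regression']} regression, "
          f"{s['correct_by_group']['persistence']} persistence)")

tree = fit_two_node_tree(learning)
print(f"tree root: {tree.root.accession}, runner-up competitor: "
      f"{tree.competitor_ranking[1][0]}")

entries = logistic_rank(learning)
print(f"logistic ranking: {[e.accession for e in entries]}; "
      f"top marker separated={entries[0].separated}")
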