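"""Greedy chain induction on synthetic data with a planted feature order.

The generator preset gives the four features strictly ordered separabilities
(SPP best, then ExAC, NDamage, COMMON) with the root restricted to the two
consensus ensembles; the greedy builder should recover exactly that chain,
and its accuracy should tie the exhaustive search over all twelve
root-restricted orderings.
"""

from varchain import (
    build_greedy,
    discretize_all,
    exhaustive_best,
    generate,
)
from varchain.simulate import planted_chain_config

cfg = planted_chain_config(n_variants=20_000, seed=7)
variants, labels = generate(cfg)
fvs = discretize_all(variants)

features = ["SPP", "ExAC", "NDamage", "COMMON"]
roots = ["SPP", "NDamage"]
topology, trace = build_greedy(fvs, labels, features, roots, max_depth=4)
best = exhaustive_best(fvs, labels, features, roots, depth=4)

print(f"greedy chain:     {topology.name}  ({trace.stopping_reason.value})")
print(f"exhaustive chain: {best.name}\n")
print("per-level candidate accuracies (chosen feature marked *):")
for depth, lv in enumerate(trace.levels, start=1):
    cells = "  ".join(
        f"{'*' if f == lv.chosen else ' '}{f}={acc:.4f}"
        for f, acc in sorted(lv.candidate_accuracy.items())
    )
    print(f"  level {depth}: {cells}")

print("\nAccuracy rises level over level because each added filter "
      "reclassifies some surviving neutral variants while losing almost no "
      "true pathogenics; all twelve full-depth orderings share the same "
      "final label set (the chain is a conjunction), so the exhaustive "
      "search can only differ in the order of exits, not in accuracy.")
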