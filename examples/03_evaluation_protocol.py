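"""The full evaluation protocol on a demonstration dataset.

Generates a curated-set-like synthetic cohort (57% pathogenic), evaluates
the reference chain with Monte Carlo subsampling (1000 draws of 30%),
stratified 10-fold cross-validation, the per-level report, and the pairwise
φ associations of the four variables.
"""

from varchain import (
    demo_clinvar_like_config,
    discretize_all,
    generate,
    kfold_cv,
    level_report,
    monte_carlo,
    phi_coefficient,
    proposed_topology,
)

cfg = demo_clinvar_like_config(n_variants=30_000, seed=0)
variants, labels = generate(cfg)
fvs = discretize_all(variants)
topo = proposed_topology()

mc = monte_carlo(fvs, labels, topo, fraction=0.3, replicates=1000, seed=0)
print("Monte Carlo (1000 x 30% subsamples), percent mean (std):")
for name, label in [("accuracy", "accuracy"),
                    ("rate_N_given_0", "pred N | class 0 (true neutral)"),
                    ("rate_P_given_0", "pred P | class 0 (false pathogenic)"),
                    ("rate_N_given_1", "pred N | class 1 (false neutral)"),
                    ("rate_P_given_1", "pred P | class 1 (true pathogenic)")]:
    print(f"  {label:36s} {100 * mc.mean[name]:5.1f} "
          f"({100 * mc.std[name]:.1f})")

cv = kfold_cv(fvs, labels, k=10, classifier=topo, seed=0)
print(f"\n10-fold CV accuracy: {100 * cv.mean['accuracy']:.1f} "
      f"({100 * cv.std['accuracy']:.1f})")

print("\nPer-level report (accuracy / FPR / FNR, %):")
for row in level_report(fvs, labels, topo).rows:
    print(f"  Lv.{row.level} ({row.feature:8s}) "
          f"{row.accuracy_pct:5.1f} / {row.fpr_pct:5.1f} / {row.fnr_pct:5.1f}")

print("\nPairwise phi associations:")
names = list(topo.levels)
for i, fa in enumerate(names):
    for fb in names[i + 1:]:
        phi = phi_coefficient([fv.values[fa] for fv in fvs],
                              [fv.values[fb] for fv in fvs])
        print(f"  {fa}-{fb}: {phi:+.2f}")

print("\nThe two per-class rate pairs each sum to 100%; the false-pathogenic "
      "rate falls level by level as deeper filters rescue misflagged "
      "neutrals, at the cost of a slowly rising false-neutral rate.")
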