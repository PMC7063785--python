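"""Triage a handful of annotated variants through the reference filter chain.

Each variant carries calls from SIFT/PolyPhen/PROVEAN, two population allele
frequencies, and nine damage-predictor calls.  The chain exits a variant as
Neutral at the first level whose flag reads neutral-leaning; only a variant
surviving all four levels is called Pathogenic.
"""

from varchain import (
    AnnotatedVariant,
    Call,
    classify,
    discretize_variant,
    proposed_topology,
)

PATH, NEUT = Call.PATHOGENIC, Call.NEUTRAL
damage = lambda k: {f"dmg{i}": PATH if i <= k else NEUT for i in range(1, 10)}

variants = {
    "all predictors benign": AnnotatedVariant(
        "1", 1001, "A", "G", sift_call=NEUT, polyphen_call=NEUT,
        provean_call=NEUT, exac_af=1e-6, common_af=1e-6,
        damage_calls=damage(9)),
    "common in ExAC (AF 5%)": AnnotatedVariant(
        "1", 1002, "C", "T", sift_call=PATH, polyphen_call=NEUT,
        provean_call=NEUT, exac_af=0.05, common_af=1e-6,
        damage_calls=damage(9)),
    "only 3/9 damage calls": AnnotatedVariant(
        "1", 1003, "G", "A", sift_call=PATH, polyphen_call=PATH,
        provean_call=NEUT, exac_af=2e-5, common_af=1e-6,
        damage_calls=damage(3)),
    "rare, damaging everywhere": AnnotatedVariant(
        "1", 1004, "T", "C", sift_call=PATH, polyphen_call=PATH,
        provean_call=PATH, exac_af=None, common_af=None,
        damage_calls=damage(8)),
}

topo = proposed_topology()
print(f"chain: {topo.name}\n")
for desc, v in variants.items():
    fv = discretize_variant(v)
    c = classify(fv, topo)
    flags = " ".join(f"{f}={fv.values[f]}" for f in topo.levels)
    where = (f"exited Neutral at level {c.exit_level} "
             f"({topo.levels[c.exit_level - 1]})"
             if c.exit_level <= len(topo) else "survived all four levels")
    print(f"{desc:28s} [{flags}] -> {c.label.value.upper():10s} {where}")

print("\nA 1 means pathogenic-leaning: a single damaging classical call, "
      "rarity (AF <= 1e-4, or absent from the catalogue), or >= 5 damage "
      "predictors. Any 0 ends the walk as Neutral.")
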