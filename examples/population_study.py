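"""Virtual-population study: three bone-resistivity groups.

Samples a population (desk scale: 150 patients instead of 1,000), evaluates
everyone through the pipeline and aggregates outcomes per group.
"""

import numpy as np
from scipy.stats import spearmanr

import ciuq
from ciuq.study import run_population

pop = ciuq.generate_population(150, seed=11, resistivity_scheme="three-group")
df = run_population(pop)

print("group              n    specificity (mean ± SD)")
for g, sub in df.groupby("group"):
    print(f"  {g:<16} {len(sub):3d}    {sub.specificity.mean():.3f} ± {sub.specificity.std():.3f}")

r, p = spearmanr(df["lamina_length_mm"], df["specificity"])
print(f"\nSpearman(lamina length, specificity) = {r:.2f} (p = {p:.1e})")
print("Lower resistivity focuses the field (better specificity); larger"
      " cochleae separate their turns and suffer less cross-turn activation.")

res = ciuq.aggregate(df)
worst = res.per_electrode.query("score == 'cross_turn'").nsmallest(3, "mean")
print("\nlowest mean cross-turn scores:")
print(worst[["group", "contact", "mean"]].to_string(index=False))
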