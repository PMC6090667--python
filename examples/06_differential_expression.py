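"""Two-condition differential expression with the fivefold / padj < 0.01 rule.

Negative-binomial counts for two developmental stages, three replicates
each; 10 of 100 features carry a true 8-fold effect.
"""

import numpy as np
import pandas as pd

from srnakit.stats import chi_square_2x2, de_test

rng = np.random.default_rng(1)
n_feat, n_eff, alpha = 100, 10, 0.05
mus = rng.lognormal(np.log(150), 0.7, size=n_feat)
data = {}
for cond in ("embryo", "l4"):
    m = mus.copy()
    if cond == "l4":
        m[:n_eff] *= 8.0
    for r in range(3):
        data[f"{cond}{r}"] = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * m))
counts = pd.DataFrame(data, index=[f"mir-{i}" for i in range(n_feat)])

results = de_test(
    counts,
    condition_a=["embryo0", "embryo1", "embryo2"],
    condition_b=["l40", "l41", "l42"],
)
up = [r for r in results if r.call == "up"]
down = [r for r in results if r.call == "down"]
print(f"{len(up)} features up in L4, {len(down)} down "
      f"(thresholds: |fold| >= 5, BH padj < 0.01)")
for r in sorted(up, key=lambda r: r.padj)[:3]:
    print(f"  {r.feature}: log2FC={r.log2fc:+.2f} padj={r.padj:.2e}")

# A 2x2 enrichment question — are up-called features over-represented in
# some category (here: the first half of the panel)? — uses the plain
# Pearson chi-square:
in_cat = sum(1 for r in up if int(r.feature.split("-")[1]) < 50)
table = [[in_cat, len(up) - in_cat], [50 - in_cat, 50 - (len(up) - in_cat)]]
stat, p = chi_square_2x2(table)
print(f"category enrichment: chi2={stat:.2f}, p={p:.3g}")
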