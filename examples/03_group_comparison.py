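"""Normality-gated group comparison and fold change of medians.

Two groups are compared with a Welch t-test only if both pass Shapiro-Wilk
at 0.05; otherwise the non-parametric Mann-Whitney U test is used. Effect
size is the fold change of medians (always >= 1, with a direction).
"""

import numpy as np

from evsecretome import TestPolicy, compare, fold_change

# the cortex Petri-dish maturation contrast, from the published medians
fc = fold_change(6.69e6, 4.02e6)
print(f"printed medians 6.69e6 -> 4.02e6: fold {fc.fold} ({fc.direction})")

rng = np.random.default_rng(0)
baseline = rng.lognormal(mean=np.log(6.7e6), sigma=0.8, size=21)
mature = rng.lognormal(mean=np.log(4.0e6), sigma=0.8, size=21)
res = compare(baseline, mature, TestPolicy(alpha=0.05), labels=("3 DIV", "9 DIV"))
print(f"test used: {res.test_used} (skewed data fail the normality gate)")
print(f"p = {res.p_value:.4f}, alpha = {res.alpha}, significant = {res.significant}")
print(f"fold change of medians: {res.fold_change.fold} ({res.fold_change.direction})")
for label, s in zip(res.group_labels, res.summaries):
    print(f"  {label}: n={s.n} median={s.median:.3g} IQR={s.iqr:.3g} "
          f"whiskers [{s.p10:.3g}, {s.p90:.3g}]")

# Bonferroni: five comparisons at nominal 0.05 -> effective level 0.01
res_adj = compare(baseline, mature, TestPolicy(alpha=0.05, bonferroni_m=5))
print(f"with bonferroni_m=5 the effective alpha is {res_adj.alpha}")
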