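# evsecretome

Post-processing and statistics for **size-classified extracellular-vesicle
(EV) secretion profiling** of neuronal cultures, for researchers who profile
conditioned media by dynamic light scattering (DLS) and want reproducible,
auditable numbers out of it: per-class secretion rates, box-plot summaries,
normality-gated significance tests and fold changes of medians — plus
supporting calculations for cryo-EM vesicle censuses, diffusive EV transport
in microfluidic junction channels, and miRNA screening rules.

## The model

EVs are classified purely by hydrodynamic radius *r* into four classes with
deliberately overlapping closed intervals (nm):

| class | radius interval |
|---|---|
| exomere | [15, 30] |
| exosome | [25, 75] |
| microvesicle | [50, 500] |
| apoptotic body | [500, 2500] |

A DLS export is a count rate *c(rᵢ)* on a radius grid. Per-class raw counts
are `C_k = Σ_{rᵢ ∈ class k} c(rᵢ)`; a grid radius inside an overlap (e.g.
62.443 nm) is counted once in **each** containing class. Raw counts become
relative secretion rates via

```
rate_k = C_k · (V_media/V_collected) · (V_resusp/V_aliquot) · dilution
              / (cell_seed_density · collection_days)
```

(default volume chain 2000/500 · 50/10 · 50 = 1000). Groups are summarized
by median, IQR and 10th/90th percentiles; two groups are compared by a Welch
t-test when both pass Shapiro-Wilk at 0.05 and by Mann-Whitney U otherwise
(exact null for small tie-free samples), three or more by Kruskal-Wallis;
multiplicity is handled by testing at α/m (Bonferroni). Effect size is the
fold change of medians, max(m₁,m₂)/min(m₁,m₂), with a direction label.

Also included: Stokes-Einstein diffusion `D = k_B·T/(6πηr)` with the 1-D
channel transit time `t = L²/(2D)`, an exclusive-assignment cryo-EM census,
and the miRNA rules (median-of-ratios size factors; expressed = normalized
count ≥ 5 in ≥ 3 samples; differential = p_adj ≤ 0.05 and |fold| ≥ 1.5).

Because raw per-radius exports for the original cultures are not publicly
deposited, the package ships a synthetic-experiment generator
(`simulate_experiment`) that reproduces the study's structure — per-class
lognormal radius mixtures calibrated to designed rate medians, ≥ 3
biological replicates × 7 DLS measurements, multiplicative lognormal noise —
so every pipeline stage is testable end to end.

## Worked example

```python
from evsecretome import (ConditionSpec, ExperimentDesign, fold_change,
                         profiles_to_rates, simulate_experiment)

targets_3div = {"exomere": 6.69e6, "exosome": 1.72e7,
                "microvesicle": 9.11e6, "apoptotic_body": 2.67e6}
targets_9div = {**targets_3div, "exomere": 4.02e6}   # designed 1.66-fold drop
conds = tuple(ConditionSpec("cortex", "petri", "dish", div, "pre", 0.0, t, 5e5, 3.0)
              for div, t in ((3, targets_3div), (9, targets_9div)))
design = ExperimentDesign(conditions=conds, n_bio=10, noise_cv=0.3)

table = profiles_to_rates(simulate_experiment(design, seed=1))
m3 = table.loc[table["div"] == 3, "exomere"].median()
m9 = table.loc[table["div"] == 9, "exomere"].median()
print(fold_change(m3, m9))
```

prints

```
FoldChange(fold=1.65, direction='decrease', defined=True)
```

i.e. a 140-measurement simulated experiment designed around the cortex
maturation medians (exomere rate dropping from 6.69×10⁶ to 4.02×10⁶ between
3 and 9 days in vitro) recovers the designed 1.66-fold decrease to within
the sampling error of the medians. The `examples/` directory has one short
script per capability (classification and binning, rate normalization,
gated comparisons, simulation, cryo-EM census, channel diffusion, miRNA
screening); each prints the numbers it computes and what they mean. A thin
CLI mirrors the library: `evsecretome classify|rates|compare|simulate|
census|diffuse|mirna --help`.

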