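"""miRNA screening: size factors, expression filter, DE thresholds.

Library sizes are equalized by median-of-ratios size factors; a miRNA is
"expressed" if at least 3 samples show a normalized count >= 5; differential
expression requires p_adj <= 0.05 AND |fold change| >= 1.5 jointly.
"""

import numpy as np
import pandas as pd

from evsecretome import filter_expressed, flag_differential, size_factors

rng = np.random.default_rng(0)
depth = np.array([0.5, 1.0, 1.0, 2.0])  # sample 0 shallow, sample 3 deep
counts = pd.DataFrame(rng.poisson(rng.uniform(2, 300, (30, 1)) * depth),
                      index=[f"mir{i}" for i in range(30)],
                      columns=["s0", "s1", "s2", "s3"])
factors = size_factors(counts)
print("size factors:", factors.round(3).to_dict())
print("(they track the designed sequencing depths 0.5 : 1 : 1 : 2)")

kept = filter_expressed(counts, factors, min_count=5, min_samples=3)
print(f"expressed miRNAs: {len(kept)} of {len(counts)}")

records = flag_differential([
    ("mir-strong-up", 1.0, 0.04),    # fold 2.0, p ok   -> significant
    ("mir-tiny-shift", 0.2, 0.001),  # fold 1.15 < 1.5  -> not significant
    ("mir-unsure", 3.0, 0.06),       # p too large      -> not significant
    ("mir-strong-down", -1.2, 0.01),
])
for r in records:
    print(f"{r.mirna_id:>16s}: log2FC {r.log2_fold_change:+5.2f}, "
          f"padj {r.p_adj:.3f} -> significant={r.significant}")
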