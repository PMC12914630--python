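"""Normalize class counts to relative per-cell per-day secretion rates.

A DLS reading sees a 10 uL aliquot (diluted 1:50) of a 50 uL EV isolate that
came from 500 uL of 2 mL conditioned media. The volume chain rescales the
reading to the whole culture; dividing by seeding density and conditioning
days yields a relative secretion rate comparable across samples.
"""

import numpy as np

from evsecretome import (DLSProfile, SampleMetadata, VolumeChain, bin_profile,
                         normalize, volume_scale)

chain = VolumeChain()  # 2000/500 * 50/10 * 50
print(f"volume scale factor: {volume_scale(chain):g}  (whole-culture equivalent)")

meta = SampleMetadata(sample_id="demo", region="hippocampus", platform="petri",
                      compartment="dish", div=3, condition="pre", timepoint_h=0.0,
                      n_bio=1, n_meas=1, cell_seed_density=5e5,
                      collection_interval_days=3.0)
profile = DLSProfile(metadata=meta, grid=np.array([20.0, 40.0, 200.0]),
                     count_rate=np.array([1200.0, 3500.0, 800.0]))
record = normalize(bin_profile(profile), chain)
for name, rate in record.rates.items():
    print(f"{name:>15s}: {rate:10.4g}  relative counts / cell density / day")
print("Rates scale linearly with counts and inversely with cell density and")
print("collection days; the absolute factor cancels in fold-change comparisons.")
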