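"""Spectral-count offset and normalization.

All counts get a +1 offset (an undetected protein then has count 1, so
"<= 1 versus > 1" is a detection rule).  Each entry is then rescaled by
its sample total relative to the group-average total.  Two modes exist:
``as_printed`` multiplies by sample_sum / group_avg (the formula exactly
as published); ``depth_corrected`` inverts the ratio so deeper runs are
scaled *down* — the conventional depth correction.
"""

import numpy as np

from spcregress import SpectralCountMatrix, add_offset, normalize_spc

m = SpectralCountMatrix(
    counts=np.array([[1, 3], [0, 5]]),  # raw counts, sample t2 is "deeper"
    protein_ids=["P1", "P2"],
    sample_ids=["t1", "t2"],
    group_of={"t1": "regression", "t2": "regression"},
)
off = add_offset(m)
print("offset counts:\n", off.counts)

for mode in ("as_printed", "depth_corrected"):
    norm = normalize_spc(off, mode=mode)
    print(f"\nmode={mode}")
    print("  sample sums:", norm.sample_sums, " group avg:", norm.group_avg)
    print("  normalized:\n", np.round(norm.values, 3))
# In depth_corrected mode the deeper sample's values shrink toward the
# group mean; in as_printed mode they grow — the published formula's
# ratio runs the other way, which is why both readings are provided.
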