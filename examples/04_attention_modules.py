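"""The two attention mechanisms at the core of the detector.

CSAAM gates a feature map by channel then by position and adds the result
back residually; with all gate weights zeroed both sigmoids sit at 0.5 and
the block reduces to Y = 1.25 X exactly.  Deformable attention samples
keys/values at learned offsets from a uniform reference grid; the offsets
are tanh-bounded.
"""

import numpy as np

from vegdet import nn
from vegdet.csaam import CSAAM
from vegdet.dat import DeformableAttention

rng = np.random.default_rng(0)
nn.set_init_seed(0)

x = rng.standard_normal((1, 16, 8, 8)).astype(np.float32)
block = CSAAM(16)
block.zero_init_()
y = block(nn.Tensor(x)).data
print("CSAAM zero-init: max |Y - 1.25 X| =", float(np.abs(y - 1.25 * x).max()))

da = DeformableAttention(16, heads=4, offset_range_factor=0.5)
points, ref = da.sampling_points(nn.Tensor(x))
drift = np.abs(points.data[0] - ref).max()
print(f"deformable attention: {len(ref)} sampling points, "
      f"max |offset| = {drift:.4f} (bound 0.5)")
out = da(nn.Tensor(x))
print("output tokens:", out.shape, "(one refined vector per query position)")
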