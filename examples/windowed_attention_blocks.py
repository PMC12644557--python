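"""Tour of the attention-branch primitives on tiny grids.

Shows the additive relative-position bias (row term + column term), the
shifted-window partition with its cross-boundary mask, and that a Swin
block with zeroed output projections is the identity map (everything else
is residual).
"""

import numpy as np

from seformer import core_blocks as cb
from seformer.nn.tensor import Tensor

# additive relative-position bias for a 2x2 window
er = np.array([-1.0, 0.0, 2.0])   # row-offset terms, offsets -1, 0, +1
ec = np.array([3.0, 0.0, -2.0])   # column-offset terms
B = cb.relpos_bias_matrix(er, ec, 2).data
print("relative-position bias, M=2 (B[i,j] = Er[dr] + Ec[dc]):")
print(B, "\n")

# shifted window partition of a 4x4 grid labelled 0..15
t = Tensor(np.arange(16, dtype=float).reshape(1, 4, 4, 1))
win, geom = cb.window_partition(t, cb.WindowLayout(2, 1))
print("4x4 grid, M=2, shift 1 -> 4 windows (cyclic shift by (-1,-1)):")
print(win.data[:, :, 0].astype(int))
mask = cb.window_attention_mask(4, 4, cb.WindowLayout(2, 1))
print(f"\ncross-boundary mask: {int((mask < 0).sum())} of {mask.size} "
      "logit pairs forbidden (tokens that were not neighbours before the shift)")
back = cb.window_reverse(win, geom)
print("window_reverse undoes the partition exactly:",
      bool(np.array_equal(back.data, t.data)))

# a block with zeroed output projections is the identity
blk = cb.SwinBlock(4, 2, cb.WindowLayout(2, 1))
blk.initialize(np.random.default_rng(0))
blk.attn.wo.weight.data[...] = 0
blk.attn.wo.bias.data[...] = 0
blk.mlp.fc2.weight.data[...] = 0
blk.mlp.fc2.bias.data[...] = 0
x = np.random.default_rng(1).standard_normal((1, 4, 4, 4)).astype(np.float32)
print("zeroed projections -> block(x) == x:",
      bool(np.allclose(blk(Tensor(x)).data, x, atol=1e-6)))
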