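"""Build the dual-branch model and its ablation variants; count parameters.

Constructs each variant under the reduced desk-scale configuration
(D=24, 128x128 input), runs one forward pass, and prints the parameter
census.  The ordering full > skip_fusion > no_cross_attention >
se_conv_only > se_swin_only mirrors the architecture's ablation study:
each removed subsystem strictly shrinks the model.
"""

import numpy as np

from seformer.model import ModelConfig, VARIANTS, build_model, count_parameters

cfg = ModelConfig.reduced()
x = np.random.default_rng(0).random((1, 3, 128, 128), dtype=np.float32)

print(f"input 128x128, base attention dim D={cfg.dim}, "
      f"conv channels {cfg.conv_channels}, window {cfg.window}\n")
print("variant               parameters   output shape")
for variant in VARIANTS:
    model = build_model(cfg, variant)
    out = model(x)
    print(f"{variant:<20} {count_parameters(model):>11,}   {out.shape}")

model = build_model(cfg, "full")
feats = model.pyramid_features(np.asarray(x))
print("\npyramid of the full model (H/4 -> H/8 -> H/16 schedule):")
for k in ("c1", "c2", "c3", "s1", "s3", "g"):
    print(f"  {k}: {tuple(feats[k].shape)}")
print("\nc* are conv-branch maps, s* attention-branch token grids; g is the "
      "pooled global vector that gates the decoder.")
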