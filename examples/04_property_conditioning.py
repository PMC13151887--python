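"""Property conditioning: encodings, cross-attention, gated fusion.

Target properties are turned into a k×d context matrix by a small transformer;
the denoiser attends to it at designated layers, so supplying targets changes
the denoiser output while the unconditioned pass is untouched.
"""

import numpy as np

from paretodiff.conditioning import (ConditioningConfig, encode_properties,
                                     sinusoidal_encode)
from paretodiff.diffusion import DenoiserConfig, EquivariantDenoiser

print("sinusoidal encoding of p=0 (first 6 slots):",
      np.array(sinusoidal_encode(0.0, 64))[:6].round(3))

# condition at an interior layer so the context reaches both the coordinate
# and the categorical heads downstream
cfg = DenoiserConfig(n_layers=3, hidden=16,
                     conditioning=ConditioningConfig(conditioned_gnn_layers=(2,),
                                                     model_dim=32, heads=2,
                                                     transformer_layers=1))
den = EquivariantDenoiser(cfg)
params = den.init_params(np.random.default_rng(0))

targets = {"qed": 0.8, "mw": 350.0, "ring_count": 2}
ctx = encode_properties(params["conditioning"], targets, cfg.conditioning)
print("context matrix:", np.array(ctx).shape,
      "(one 32-dim token per requested property)")

rng = np.random.default_rng(3)
x = rng.standard_normal((6, 3))
onehot = np.eye(6)[rng.integers(0, 6, 6)]
free = den.forward(params, x, onehot, 0.5)
cond = den.forward(params, x, onehot, 0.5, context=ctx)
shift = np.abs(np.array(cond[0]) - np.array(free[0])).max()
print(f"max |Δε̂| between unconditioned and conditioned pass: {shift:.4f} "
      "(the context steers the predicted noise)")

swapped = encode_properties(params["conditioning"],
                            dict(reversed(list(targets.items()))), cfg.conditioning)
print("order-insensitive encoder: max |Δcontext| after permuting targets =",
      f"{np.abs(np.array(ctx) - np.array(swapped)).max():.1e}")
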