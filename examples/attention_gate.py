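"""What the channel-attention gate does to a feature map.

Per-channel global max and mean descriptors pass through a shared
two-layer MLP; their sum is squashed by a sigmoid into per-channel
weights S_a in (0,1) that rescale the map.  Strong channels keep most
of their signal, weak ones are suppressed — and the output can never
exceed the input in magnitude.
"""

import numpy as np

from pestseg import attention_forward, attention_weights, init_attention_params

rng = np.random.default_rng(1)
g = rng.normal(size=(8, 8, 8)) * np.linspace(0.1, 2.0, 8)  # channels of growing energy
params = init_attention_params(channels=8, reduction=4, rng=rng)

s_a = attention_weights(g, params)
out = attention_forward(g, params)
print("channel   input |max|   gate S_a   output |max|")
for c in range(8):
    print(f"   {c}        {np.abs(g[:, :, c]).max():6.3f}     {s_a[c]:.3f}      {np.abs(out[:, :, c]).max():6.3f}")
print(f"\nall gates in (0,1): {bool(np.all((s_a > 0) & (s_a < 1)))}; "
      f"contraction |out| <= |in|: {bool(np.all(np.abs(out) <= np.abs(g)))}")
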