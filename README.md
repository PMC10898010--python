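# pestseg

Binary segmentation of crop insect pests in field images, built around a
**dilated multi-scale attention U-Net**: a U-Net whose encoder/decoder
blocks are dilated Inception modules and whose skip connections pass
through channel-attention gates. The package is aimed at researchers in
agricultural image analysis who need a fully inspectable, exactly
reproducible reference implementation of this architecture family — it
is pure numpy (with a built-in reverse-mode autodiff tape), so every
tensor, gradient and update is a plain array you can look at.

## The model in brief

Pests in the field vary in size by more than an order of magnitude, so
each feature block sees three receptive-field scales at once. A 3×3
kernel dilated at rate *r* covers an effective footprint

```
k_s = k + (k − 1)(r − 1)        (3, 5, 7, 9 px at r = 1..4)
```

with the same 9 weights, growing the receptive field by (k_s/k)².
Each block runs three 1×1-bottlenecked branches at rates 1/2/3, plus a
global-average-pool → 1×1 conv → bilinear-upsample context path, and
fuses everything (plus the block input, a residual route) with a 1×1
convolution. On each skip connection, per-channel global max/mean
descriptors drive a shared two-layer MLP whose sigmoid output
S_a ∈ (0,1) rescales the skip channels before concatenation.

Training minimises the compound objective

```
Loss = L_IoU + L_bce
```

(soft Jaccard + weighted binary cross-entropy), and evaluation reports
ACC = TP/(TP+FN) and IoU = TP/(TP+FP+FN) over pooled pixel confusion
counts. Six variants (`unet`, `unet_attn`, `unet_inception`,
`unet_dilated_ms`, `unet_inception_attn`, `dmsaunet`) toggle the block
type and the gates for ablation; a fuzzy c-means baseline and a seeded
synthetic pest-image generator complete the pipeline, so everything is
testable end to end without external data. See `docs/methods.md` for
the full account.

## Worked example

`examples/train_segmenter.py` trains a small `dmsaunet` (32×32 inputs,
depth 2, base width 4) for 300 Adam steps on ten synthetic pest images
and prints:

```
model: dmsaunet, 3904 trainable parameters
loss: 1.624 (start) -> 0.094 (median, last 30 steps)
training-set ACC = 0.975, IoU = 0.968
(ACC is the recall-form TP/(TP+FN); IoU is the Jaccard index over pixels)
```

The starting loss sits near its theoretical untrained value
(ln 2 ≈ 0.69 from the BCE term plus the soft-IoU of a half-map); after
300 steps the net reproduces its training masks almost exactly —
97.5 % of pest pixels recovered, Jaccard overlap 0.968. The other
example scripts each demonstrate one capability
(`receptive_field.py`, `attention_gate.py`, `generate_dataset.py`,
`fcm_baseline.py`) and print a line explaining their numbers.

The same functionality is available from the shell:

```bash
pestseg generate --seed 1 --out data/          # synthetic dataset + manifest
pestseg train    --seed 1 --data data/         # checkpoint + loss history
pestseg cv       --seed 1 --data data/ --k 5   # 5-fold cross-validation
pestseg ablate   --variants unet,dmsaunet ...  # shared-fold comparison table
pestseg predict  --checkpoint m.ckpt.npz --in img.png --out mask.png
pestseg inspect-rf --k 3 --rates 1,2,3,4       # receptive-field algebra
```

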