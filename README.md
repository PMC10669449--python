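# dafdnet

Direction-aware detection of thin, low-contrast fracture lines in grayscale
radiograph-like images.

Nondisplaced femoral-neck fractures show up on pelvis radiographs as faint,
thin, slightly curved dark lines — exactly the kind of structure that
vanishes under a generic encoder–decoder's repeated down-sampling, and a
frequent source of missed diagnoses. `dafdnet` implements a segmentation
network built around that failure mode, the two-phase
localization-then-detection pipeline it sits in, the region-overlap
evaluation suite, and a synthetic phantom generator that makes the whole
system testable end-to-end without any clinical data. It is aimed at
researchers in medical image analysis who want a fully reproducible,
CPU-only reference implementation of direction-aware thin-structure
segmentation.

## The model

The network is an encoder–decoder with **two parallel encoder paths** over a
single-channel image:

- a **Gabor path**: a fixed (non-learned) bank of Gabor wavelets

  `G(z) = (|k|²/σ²) · exp(−|k|²|z|²/(2σ²)) · (e^{i k·z} − e^{−σ²/2})`

  with σ = 2π, k_v = (π/2)/2^{v−1} (v = 1..4) and φ_u = uπ/8 (u = 0..7) —
  32 orientation/frequency band-pass channels whose magnitude responses
  flag oriented lines regardless of where the fracture happens to point;

- a **ghost path**: stacked SE-ghost modules (a ghost convolution whose
  cheap branch is squeeze-and-excitation channel reweighting of the primary
  convolution) at 32/64/128 channels over three resolutions.

Per stage the paths are concatenated, refined (2×2 average pool → 3×3 conv
→ batch norm → 2× upsample), and passed through channel-then-spatial
attention; the decoder walks back up to a one-channel sigmoid probability
map at input resolution. Training minimizes pixelwise mean-squared error
against the binary mask with Adam under a stepped warm-up
(1e−5 → 4e−5 in 1e−5 steps).

Detection runs in two phases: a first network segments the femoral-neck
region, the image is cropped to its padded bounding box, and a second
network segments the fracture line inside the crop; boxes map back to
full-image coordinates exactly. Evaluation reports rectangle IOU plus mask
Dice = 2|A∩B|/(|A|+|B|) and Jaccard = |A∩B|/|A∪B|, with binned summaries.

Because no deep-learning framework is required, the network runs on a small
reverse-mode autodiff engine included in the package (pure float32 numpy;
every layer gradient is verified against central differences in the tests).

## Worked example

Train the reduced configuration on 64 synthetic phantoms (128 px, crack
width 3 px, contrast 0.08–0.15) and score 32 unseen phantoms — about four
minutes on one CPU:

```python
import numpy as np
from dafdnet import (NetworkConfig, PhantomSpec, TrainConfig, build_dafdnet,
                     dice, generate_phantom, train)

def phantoms(n, seed):
    rng = np.random.default_rng(seed)
    return [generate_phantom(PhantomSpec(
        image_size=128, seed=int(rng.integers(2**31)), crack_width=3,
        crack_contrast=float(rng.uniform(0.08, 0.15)))) for _ in range(n)]

train_set, test_set = phantoms(64, 100), phantoms(32, 999)
cfg = NetworkConfig(input_size=128, stage_channels=(8, 16, 32),
                    pf_channels=(8, 16, 32), gabor_scales=(1, 2))
model = build_dafdnet(cfg, seed=0)
pairs = [(r.image, r.fracture_mask.astype(np.float32)) for r in train_set]
model, history = train(model, pairs, TrainConfig(
    batch_size=8, epochs=22, lr_init=2e-3, lr_max=2e-3, lr_step=0.0, seed=0))
scores = [dice(model.predict(r.image) >= 0.5, r.fracture_mask) for r in test_set]
print(f"final training loss: {history.train_loss[-1]:.4f}")
print(f"mean test Dice over 32 unseen phantoms: {np.mean(scores):.3f}")
```

```
final training loss: 0.0004
mean test Dice over 32 unseen phantoms: 0.937
```

The final loss is far below the all-background baseline (the mean
foreground fraction, ≈ 0.01), i.e. the network is segmenting the crack, not
just predicting "no fracture"; a mean Dice of 0.94 on unseen phantoms means
predicted crack pixels and ground truth overlap almost completely. These
numbers describe the synthetic task only — phantoms emulate the
contrast/geometry regime of the clinical problem, not real anatomy.

The direction-awareness itself is directly observable: filter a phantom
whose crack orientation is known and ask which orientation channel responds
most along the crack:

```python
import numpy as np
from dafdnet import PhantomSpec, generate_phantom, make_gabor_bank, gabor_conv

rec = generate_phantom(PhantomSpec(image_size=128, seed=7,
                                   crack_orientation=1.1, crack_contrast=0.12,
                                   crack_width=3))
bank = make_gabor_bank(scales=(1,))
resp = np.abs(gabor_conv(rec.image, bank))
best = int(resp[rec.fracture_mask].mean(axis=0).argmax())
print(f"crack orientation: {rec.meta['crack_orientation']:.2f} rad")
print(f"strongest channel: u={best}, preferred line angle "
      f"{bank.preferred_line_angle(best):.2f} rad")
```

```
crack orientation: 1.10 rad
strongest channel: u=7, preferred line angle 1.18 rad
```

## Command line

```sh
dafdnet generate --n 8 --out data/ --seed 1 --image-size 64 --variants 2 --split 0.5
dafdnet train --data data/ --target roi      --out roi.npz  ...
dafdnet train --data data/ --target fracture --out frac.npz ...
dafdnet predict --image data/images/000000.png --roi-model roi.npz \
                --frac-model frac.npz --out det.json --overlay det.png
dafdnet evaluate --pred-dir pred/ --label-dir labels/ --out scores.csv
```

`generate` writes images, both mask sets and a JSON-lines manifest;
`predict` emits the detected boxes, flags and peak probability as JSON
(plus an optional overlay PNG with the label box in red and the prediction
in yellow); `evaluate` writes per-image and summary CSVs. A smoke-scale run
of the full loop (8 base phantoms at 64 px, 60 epochs per stage, ~40 s of
training) detects the fracture on a held-in image:

```
{"found_roi": true, "found_fracture": true, "fracture_box_crop": [29, 39, 30, 41],
 "fracture_box_full": [31, 36, 32, 37], "crop_box": [14, 19, 52, 44],
 "max_probability": 0.6846415996551514}
```

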