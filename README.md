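# sfnet — hybrid edge-guided bone-fracture classification

`sfnet` classifies radiograph-like grey images as **fracture** vs.
**healthy**. It is aimed at researchers studying lightweight, edge-guided
image classifiers for skeletal X-rays — settings where fracture lines are
weak, low-intensity discontinuities that plain CNNs under-weight.

The method has two parts:

1. **An improved Canny edge detector** that localizes fracture edges:
   a median pre-filter (robust to impulse noise, preserves weak steps),
   3×3 Sobel gradients `G = √(Gx² + Gy²)`, `θ = atan2(Gy, Gx)`, **adaptive**
   double thresholds read off the gradient-magnitude histogram (the high
   threshold sits at the foot of the steepest falloff after the histogram's
   global peak; `low = 0.5·high`), four-sector non-maximum suppression and
   hysteresis linking.
2. **A two-stream CNN ("SFNet")**: the grey image and its edge map each feed
   a six-block conv stack (widths 16→512, each block
   `conv 3×3 → ReLU → batch-norm → 2×2 avg-pool`, with local response
   normalization `b_j = a_j/(t + αΣa_i²)^β` after the first two blocks),
   global average pooling to a 512-vector per stream, fusion by
   concatenation `F = A ⊕ V` (1024-dim), then
   `dense(1024) → ReLU → dropout → dense(2) → softmax`. The default build has
   4,201,218 trainable parameters (≤ 5×10⁶).

Training uses Adam at 3×10⁻³ (RMSprop available), batch 32, 20 epochs, a
stratified seeded 80/20 split, and best-validation-checkpoint retention.
Because no clinical images ship with the package, a **phantom generator**
renders bright bone-like shafts on dark noisy backgrounds with fractures as
transverse dark gaps, which makes every stage testable end to end.

The network layers and optimizers are implemented in numpy (im2col
convolutions through BLAS, analytic backward passes); runs are
bit-reproducible given a seed.

## Worked example

```python
import numpy as np
from sfnet import (PhantomSpec, generate_dataset, split_dataset, train,
                   build_sfnet, reduced_config, TrainConfig, improved_canny)

spec = PhantomSpec(side=64, noise_sigma=0.05)        # bone-like phantoms
ds = generate_dataset(250, template=spec, seed=42)    # 250 per class
split = split_dataset(ds, ratio=0.8, seed=0)          # stratified 400/100

img, label = ds.items[0]
print(label, int(improved_canny(img).sum()))          # edge pixels found

model = build_sfnet(reduced_config(64), seed=0)       # desk-scale build
history = train(model, split, TrainConfig(epochs=10, seed=0))
print(round(max(history["val_acc"]), 3))
```

This prints, in order:

```
fracture 873
1.0
```

— the fractured phantom's edge map has 873 edge pixels (the shaft borders,
the gap's transverse edges, and residual noise responses at this noise
level), and the reduced two-stream model separates the
100 held-out phantoms perfectly (best validation accuracy 1.0), which is
expected: the phantoms are separable by construction. See
`docs/methods.md` for what this does and does not demonstrate.

The same flows are scriptable from the shell:

```bash
sfnet synth --n 200 --side 64 --out data/
sfnet edges --in data/fracture_00000.png --out edge.png
sfnet run --config run.yaml --seed 0 --out runs/demo
```

An sklearn-style estimator is also provided
(`sfnet.SFNetClassifier(...).fit(X, y).predict(X)`) for composition with
sklearn model selection.

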