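# dermoborder

Automated assessment of **skin-lesion border irregularity** — the *B*
feature of the clinical ABCD melanoma rule — from grayscale dermoscopy
images.  Benign naevi tend to present smooth, convex borders; melanoma
borders are irregular, driven by uneven growth.  `dermoborder` turns
that clinical sign into an objective, reproducible measurement and a
regular/irregular decision.

The pipeline has four stages:

1. **Segmentation** — fuzzy c-means intensity clustering
   (J = Σ_j Σ_i u_ij^m ‖x_j − v_i‖²), a type-II fuzzy *ambiguity
   threshold* found by maximizing the ultrafuzziness
   γ̃ = (1/MN) Σ_g h(g)[μ(g)^{1/α} − μ(g)^α] of a sliding S-function,
   and *gradual-focusing* defuzzification that assigns ambiguous pixels
   to the majority cluster of their committed neighbors.
2. **Border detection** — a four-step Canny detector (separable
   Gaussian, 2×2 gradient stencil, non-maximum suppression, hysteresis
   linking) followed by Moore-neighbor tracing into an ordered closed
   border.
3. **Irregularity descriptor** — 27 values per lesion: box-counting
   fractal dimension D (slope of log N(ε) vs log 1/ε), convexity
   C = hull perimeter / lesion perimeter, and the magnitudes of the 25
   Zernike moments Z_nm = (n+1)/π Σ V*_nm f up to order 8.
4. **Decision** — a Gaussian naive Bayes on the descriptor and a small
   CNN on (mask, border, descriptor), fused as
   P = (CNN_p1·GnB_p1 + CNN_p2·GnB_p2)/2 and thresholded adaptively at
   (max P + mean P)/2; P below the threshold reads *regular* (1), above
   it *irregular* (0).

A seeded synthetic-lesion generator (`dermoborder.fixtures`) provides
ground-truth masks, labels, and controllable border roughness, so the
entire pipeline is testable without any dermoscopy archive.

See `docs/methods.md` for the models, parameter choices, and
limitations in detail.

## Worked example

```python
import numpy as np
from dermoborder import fixtures, classify
from dermoborder.pipeline import PipelineConfig, train_pipeline, predict_pipeline, process_image

# one lesion through the image-analysis front end
reg = fixtures.make_regular_lesion(axes=(60, 40), contrast=120, noise_sd=8, seed=1)
res = process_image(reg.image)
print("jaccard vs truth: %.2f" % classify.jaccard_index(res.mask, reg.mask))
print("FD=%.4f  C=%.4f  ZM1=%.4f" % tuple(res.vector[:3]))

# train the ensemble and score a held-out batch
train = fixtures.make_dataset(6, 36, seed=10, balance=True)
models = train_pipeline(train, [s.label for s in train], PipelineConfig(seed=10))
test = fixtures.make_dataset(30, 30, seed=99)
records, thr = predict_pipeline(models, test)
rep = classify.evaluate([r["decision"] for r in records], [s.label for s in test])
print("accuracy=%.1f%% sensitivity=%.1f%% specificity=%.1f%% F=%.1f%%"
      % (rep.accuracy, rep.sensitivity, rep.specificity, rep.f_score))
```

prints

```
jaccard vs truth: 100.00
FD=0.9030  C=1.0000  ZM1=0.3183
accuracy=95.0% sensitivity=90.0% specificity=100.0% F=95.2%
```

The segmentation recovers the noisy ellipse's ground-truth mask
exactly (Jaccard 100%).  The descriptor behaves as the clinical sign
predicts: the smooth lesion scores low fractal dimension and convexity
1.0, while an irregular blob of roughness 0.4 drops to C ≈ 0.87 with a
higher FD; ZM1 = 0.3183 (= 1/π) is a built-in normalization check that
holds for every mask.  Trained on 6 unique regular lesions augmented
to parity against 36 diverse irregulars, the ensemble classifies 60
held-out lesions at 95% accuracy: all 30 irregular borders are caught
(specificity 100%), 3 of 30 regular borders are escalated to
irregular (sensitivity 90%).

The same flow is available from the shell:

```sh
dermoborder synth --n-regular 6 --n-irregular 36 --seed 10 --out data/train
dermoborder train --in data/train --out models
dermoborder synth --n-regular 30 --n-irregular 30 --seed 99 --out data/test
dermoborder predict --model-dir models --in data/test --out pred.csv
dermoborder evaluate --pred pred.csv --labels data/test/labels.csv --out metrics.json
```

with `segment`, `border`, and `features` exposing the intermediate
stages individually.

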