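# earcount

Segmentation and counting of wheat ears (spikes) in RGB field images, for
plant phenotyping and yield estimation.  The number of ears per unit area
is one of the three components of wheat yield; counting them from imagery
replaces slow, subjective manual field counts.

## Method

The pipeline classifies superpixel patches rather than pixels:

1. **SLIC superpixels** — localized k-means over (CIELAB, *xy*) with
   distance `D = sqrt(d_lab^2 + (d_xy/S)^2 m^2)`, grid-initialized seeds,
   2S×2S search windows and a connectivity pass.
2. **Patches** — one 20×20 window per superpixel, centred on its centroid.
   For training, a patch is background iff its superpixel contains no ear
   pixel of the ground-truth mask.
3. **Features** — the block matrix `[f1C | f2G | f3E]`: colour coherence
   vectors (CCV), gray-level co-occurrence statistics (GLCM: contrast,
   correlation, energy, homogeneity, entropy) and the MPEG-7 edge
   histogram descriptor (EHD); 228 dimensions by default.
4. **Weighting and fusion** — per-class importance `I_n = 1/(1 + k_n)`
   (with `k_n` the within-class standard deviation) and weights
   `W_jn = I_jn / Σ_n I_jn`, followed by RBF kernel PCA retaining 95% of
   the spectrum.
5. **Twin SVM** — two nonparallel kernel hyperplanes, one per class,
   obtained from the box-constrained duals of

   ```
   min 1/2 ||K(A,C')w1 + e1 b1||^2 + c1 e2'q
   s.t. -(K(B,C')w1 + e2 b1) + q >= e2,  q >= 0
   ```

   (and symmetrically for the background plane); a patch takes the label
   of the nearer plane.  Patch labels are painted back over superpixels,
   a 3×3 median filter cleans the binary mask, and 8-connected regions
   are counted — the region count is the ear count.

A seeded synthetic scene generator (textured elliptical ears on a
soil-and-leaf background, three illumination levels, four noise models,
exact masks and counts) provides ground truth for training and for all
tests.  See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import numpy as np
from earcount import SceneConfig, generate_scene, fit_model, run_pipeline
from earcount.model import TrainConfig
from earcount.pipeline import PipelineConfig

illum = ("low", "medium", "high")
train = [generate_scene(SceneConfig(seed=1000 + i, illumination=illum[i % 3]))
         for i in range(30)]
model = fit_model(train, train_config=TrainConfig(seed=0))

scene = generate_scene(SceneConfig(seed=2005, ear_count=13, illumination=illum[2]))
result = run_pipeline(scene.image, model, PipelineConfig(min_area=50))
print(result.count, scene.count)
```

prints

```
12 13
```

— the pipeline found 12 ear regions against 13 true ears in this scene.
Across 20 held-out
scenes with true counts 8–27, the same model gives a predicted-vs-true
count regression with slope ≈ 1.04 and R² ≈ 0.99, exact counts on about
half of the scenes and counts within ±3 elsewhere.

The same workflow is available from the shell:

```bash
earcount synth --out scenes/ --seed 0
earcount train --scenes scenes/ --out model.earc
earcount segment --image scenes/scene_0000_image.png --model model.earc --out seg/
earcount evaluate --pred seg_masks/ --ref ref_masks/ --out report.csv
```

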