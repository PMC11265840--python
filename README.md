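# her2pss — pyramid-sampling HER2 scoring for IHC tissue cores

`her2pss` is a Python toolkit for automated HER2 status scoring of
immunohistochemistry (IHC)-stained breast tissue cores. It is aimed at
computational-pathology researchers who want a reproducible, CPU-runnable
implementation of a multi-scale, confidence-ranked scoring protocol —
including a synthetic IHC-like image generator, so the entire pipeline can
be developed and tested without any slide data.

## The method

**Pyramid-Sampling Sets (PSS).** HER2 expression is read from membrane
staining at cellular scale, but tissue context matters too. A PSS collects
`512 × 512` RGB patches from one core image at several scales — by default
40 patches at the original resolution, 10 from a 2×-downsampled copy, and
one patch holding the whole core resized to `512 × 512` — and stacks them
along the channel axis into a single `512 × 512 × 153` classifier input
(51 patches × 3 channels). Reduced presets `a` (1 patch), `b` (27) and
`c` (29) support ablation comparisons.

**Class-weighted training.** A 4-class softmax classifier (pluggable
backbone; a small numpy convnet is the runnable default, DenseNet-201 is
the documented full-scale reference) is trained with inverse-frequency
class weights `w_c = M / (C · n_c)` and the loss

```
L = −(1/m) Σ_i Σ_c  w_c · y_{i,c} · log p_{i,c}
```

with dihedral augmentation (flips and 90° rotations) applied per patch,
AdamW, and a fresh PSS resampled for every core at every epoch.

**Replicate inference (N, k).** At test time, `N` independent PSSs are
drawn per core (default `N = 20`); each yields a class-probability vector
whose *confidence* is the top-two softmax margin `p(1) − p(2)`. The `k`
most confident predictions (default `k = 5`) form the k-Confident
Selection set (KCS), and the final score is

```
FinalHER2Score = max over the KCS of the predicted class,   0 < 1+ < 2+ < 3+.
```

Taking the maximum of the confident replicates makes the call sensitive to
small strongly-expressing regions that most random samples miss — the
characteristic failure mode of heterogeneous HER2 expression.

**Monte Carlo hyperparameter analysis.** A pool of replicate predictions
per core (300 at full scale, 30 at desk scale) is cached once; random
subsets of size `N` are replayed through the KCS/max protocol thousands of
times to map the accuracy distribution (min/median/max) as a function of
`N` and `k`. At `N = pool size` the spread is exactly zero.

Supporting modules cover TMA-slide core detection (Hough proposals with
full-resolution centroid refinement), consensus labeling from multiple
pathologists' scores (two-rater agreement, adjudication, nondiagnostic
exclusion, patient-disjoint splits), and the evaluation battery (confusion
matrix, per-class specificity `TN_i/(TN_i+FP_i)`, adjacent-pair
accuracies, and ROC/AUC for the groupings 0 vs rest, {0,1+} vs {2+,3+},
{0,1+,2+} vs 3+ from averaged top-k probabilities).

## Worked example

```python
import numpy as np
from her2pss import (CoreSpec, PyramidConfig, TrainConfig, generate_dataset,
                     predict_core, train)

config = PyramidConfig(patch_size=64, levels=((1, 8), (2, 2)))  # desk scale
cores, manifest = generate_dataset(40, CoreSpec(diameter_px=256), seed=11)
manifest["split"] = (["train"] * 32 + ["val"] * 8) * 4
images = {c.core_id: c for c, _ in cores}

model = train(manifest, config,
              TrainConfig(learning_rate=3e-3, max_epochs=60, seed=3),
              images=images, channels=(16, 32, 32, 32))

test_cores, _ = generate_dataset(20, CoreSpec(diameter_px=256), seed=999)
hits = sum(
    int(predict_core(model, core, n=10, k=3, seed=50 + i).final_score)
    == int(label)
    for i, (core, label) in enumerate(test_cores)
)
print(f"blind accuracy: {hits / len(test_cores):.3f}")
```

This trains in ~2.5 min on one CPU and prints

```
blind accuracy: 1.000
```

— on held-out synthetic cores with the default (well-separated) staining
parameters, the replicate protocol recovers every label. On cores where
only a 10–30% sector carries 3+ staining and the rest is 2+, the
max-aggregation protocol recovers the high class far more often than a
single PSS prediction (33/50 vs 12/50 cores in the pipeline run below).

The same workflow is available from the shell:

```
her2pss simulate cores --n-per-class 3 --diameter 256 --seed 9 --out cores/
her2pss train --manifest cores/manifest.csv --config default --out model.npz
her2pss predict --model model.npz --cores cores/ --n 20 --k 5 --out pred.csv
```

## The acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at desk scale (~3 min): it
generates the synthetic dataset, trains the backbone, runs replicate
inference on 80 blind cores, compares max-aggregation against single-PSS
prediction on heterogeneous cores, sweeps the Monte Carlo accuracy spread
over `N ∈ {1, 2, 5, 10, 20, 30}` at `k = 5` on a 30-replicate pool,
detects cores on a synthetic TMA mosaic, and resolves synthetic rater
scores — printing each result as it goes and writing the JSON result file
to `--out`.
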