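# immunoseg

Immune-inspired segmentation of grayscale (brain-MRI-like) images.

Delineating lesions and tissue classes on MRI slices is routinely posed as an
intensity-segmentation problem: pick a threshold, or a set of cluster centers,
that best explains the gray-level distribution. `immunoseg` implements two
clonal-selection optimizers for that problem, the evaluation metrics used to
compare them, and a synthetic phantom generator that supplies pixel-level
ground truth — so the whole pipeline is testable without clinical data.

* **AIA thresholder** — a binary Otsu thresholder. The antibody is the 8-bit
  code of a threshold *t*; the antigen affinity is the between-class variance

  σ²_b(t) = V₀(w₀ − V)² + V₁(w₁ − V)²,

  with V₀, V₁ the class proportions, w₀, w₁ the class mean gray levels and
  V = V₀w₀ + V₁w₁ the total mean. An exhaustive 256-point scan is included as
  the oracle.
* **ICA clusterer** — K-class clustering where an antibody encodes K centers
  (8 bits each). The objective is the within-cluster sum of squares
  J = Σ_j Σ_{x∈c_j} (x − D_j)², antigen affinity 1/(1+J), and the clonal
  search is hybridized with Lloyd (K-means) refinement of the elite each
  generation: global immune search chooses the basin, K-means descends in it.

Both run the same engine: affinity evaluation, elitist memory cell,
concentration D_i (fraction of the population with pairwise affinity > λ),
diversity-corrected fitness `affinity · exp(k·D_i)` with k < 0,
rank-proportional cloning, single-point crossover with a fresh random
antibody group, single-bit mutation, and seeded bit-exact reproducibility.

Segmentations are scored per class against ground truth with the
volume-fraction metrics TPVF = TP/(TP+FN), FNVF = FN/(TP+FN),
FPVF = FP/(FP+TN) and the precision rate PR = TP/(TP+FP).

## Worked example

```python
import numpy as np
from immunoseg import (ImmuneParams, PhantomSpec, aia_threshold, evaluate,
                       generate_phantom, ica_segment, order_labels_by_center)

ph = generate_phantom(PhantomSpec(height=64, width=64,
                                  class_means=(30, 90, 150, 220),
                                  noise_sigma=8.0, seed=42))
res = ica_segment(ph.image, K=4,
                  params=ImmuneParams(popsize=30, maxgen=300, seed=0))
labels, centers = order_labels_by_center(res)
report = evaluate(labels, ph.truth)
print("centers:", centers.tolist())
print("J =", res.J, " J1 =", res.J1, " generations =", len(res.trace))
print(report.per_class[["class", "PR", "TPVF", "FNVF", "FPVF"]]
      .round(4).to_string(index=False))
```

prints

```
centers: [30, 90, 150, 219]
J = 261295.0  J1 = 922935.0  generations = 21
 class  PR  TPVF  FNVF  FPVF
     0 1.0   1.0   0.0   0.0
     1 1.0   1.0   0.0   0.0
     2 1.0   1.0   0.0   0.0
     3 1.0   1.0   0.0   0.0
```

The four recovered centers sit on the phantom's true class means (30, 90,
150, 220) to within one gray level; J has dropped from the initial elite's
922935 to 261295 (the residual noise variance), and every tissue class is
recovered perfectly (all volume fractions at their ideal values). The binary
thresholder on the same image, `aia_threshold(ph.image, ImmuneParams(seed=0))`,
returns threshold 106 with between-class variance 2219.1 — it can only split
the four classes into two groups, which is exactly the comparison the
`benchmark` harness quantifies as K grows.

## Command line

```sh
immunoseg phantom --out img.png --truth truth.png --size 64 \
    --means 30,90,150,220 --sigma 8 --seed 1
immunoseg threshold img.png --out mask.png --trace trace.csv --seed 0
immunoseg segment img.png --k 4 --out labels.png --seed 0
immunoseg evaluate --pred labels.png --truth truth.png --out report.csv
immunoseg benchmark --out-dir bench/ --ks 2,3,4,5 --replicates 5 --seed 0
```

All stochastic commands take an explicit `--seed`; `--config FILE.yaml`
supplies per-subcommand defaults.

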