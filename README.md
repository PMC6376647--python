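# stackdetect

Generalized cell detection from brightfield z-stacks: train a fully
convolutional detector on **one** annotated cell line, then adapt it to
unseen cell lines **without a single new annotation** by iterative
pseudo-labeling of its own confident predictions.

## The problem

Counting cells in culture underlies growth, survival and drug-response
assays. Brightfield imaging is cheap and label-free, but cells are low
contrast in focus — their appearance only becomes distinctive out of
focus, where contrast grows with defocus and inverts its sign across the
focal plane. A detector trained on one cell line exploits this, but each
cell line has its own size, contrast and growth pattern ("domain"): on a
dissimilar line the detector typically keeps **high precision** while
losing **recall**. Those scarce-but-correct detections are good enough to
*generate* training targets, which is exactly what this package automates.

## The method

1. **Heatmap regression.** Three consecutive focal planes (the focused
   plane and the two above it) are the 3-channel input to a reduced
   U-Net — one encoder/decoder level pair removed from the canonical
   architecture (depth 3, symmetric skips, sigmoid head) — that outputs a
   full-resolution cell-confidence heatmap. Training targets are binary
   masks with a disk of radius r = 8 px per annotated centre, shrunk when
   disks would touch so each cell keeps its own component; this radius
   keeps the background:cell pixel balance near 20:1.
2. **Supervised phase.** Pixel-mean binary cross-entropy, SGD with
   Nesterov momentum 0.8, batch 5, learning rate 0.1 halved every 10
   epochs, patch size switched per 10-epoch cycle, 60 epochs, best
   validation checkpoint kept. Data are augmented (right-angle
   rotations/flips, translation jitter, intensity shifts, noise) and
   doubled by a 75 % resize (target radius 8 → 6 in the same proportion).
3. **Iterative unsupervised adaptation.** Per cycle: predict four random
   unannotated target-domain images with the current weights; mark local
   heatmap peaks (threshold 0.2, min distance 5 px) as cells; dilate them
   into radius-6 disk targets; mix these pseudo-labeled patches 50/50
   with annotated source patches; train 10 epochs. Six cycles, learning
   rate halved per cycle. The annotated half stops false predictions
   from amplifying.
4. **Scoring.** A detection counts when a ground-truth centre lies at
   Euclidean distance *d* < 20 px (closest candidate only, one-to-one);
   precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R). A
   density-stratified profile (Gaussian KDE, σ = 50 px, five equal
   density-range bins) separates sparse from crowded regions.

Because the benchmark microscopy data is not redistributable, the package
ships a synthetic focus-stack generator (`stackdetect.simulate`) whose
cells invert contrast across focus and blur with defocus, with a sparse
high-contrast source preset and a dense low-contrast clustered target
preset. Every stage of the pipeline is exercised end to end on it.

There is **no deep-learning framework dependency**: the network, its
backpropagation and the optimizer are implemented in numpy and verified
against numerical gradients in the test suite.

## Worked example

```python
from stackdetect.experiment import run_benchmark

res = run_benchmark(seed=1)   # ~5 min on one CPU core
print(f"source F1 after supervised training: {res.source_before.f1:.3f}")
print(f"target before adaptation: precision={res.target_before.precision:.3f} "
      f"recall={res.target_before.recall:.3f} F1={res.target_before.f1:.3f}")
print(f"target F1 after 6 adaptation cycles: {res.target_after.f1:.3f}")
print(f"source F1 after adaptation: {res.source_after.f1:.3f}")
```

prints

```
source F1 after supervised training: 0.920
target before adaptation: precision=1.000 recall=0.236 F1=0.382
target F1 after 6 adaptation cycles: 0.975
source F1 after adaptation: 0.987
```

Read: the detector is accurate on its own domain (F1 0.92); on the
dissimilar target domain it finds only a quarter of the cells but
everything it finds is right (the high-precision/low-recall regime that
makes auto-labeling safe); six cycles of pseudo-labeling lift target F1
from 0.38 to 0.97 while the source domain, whose annotated patches stay
in the training mix, does not degrade.

The same pipeline is scriptable from the shell:

```bash
stackdetect simulate --preset sourcelike --n 12 --seed 1 --out-dir data/source
stackdetect simulate --preset targetlike --n 8  --seed 2 --out-dir data/target
stackdetect train  --images data/source --annotations data/source \
                   --config configs/desk.yaml --out-checkpoint runs/supervised.npz
stackdetect adapt  --checkpoint-in runs/supervised.npz \
                   --source-images data/source --source-annotations data/source \
                   --target-images data/target --config configs/desk.yaml \
                   --checkpoint-out runs/adapted.npz
stackdetect detect --checkpoint runs/adapted.npz --stack data/target/stack_000.tif \
                   --config configs/desk.yaml --out-csv runs/det_000.csv
stackdetect evaluate --detections runs/det_000.csv \
                     --ground-truth data/target/stack_000.csv --density
```

Every command writes a `run_manifest.json` (config + seed + versions)
next to its outputs. See `configs/desk.yaml` for the desk-scale settings
used above; defaults without a config file are the full-scale values.

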