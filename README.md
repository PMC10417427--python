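# csrseg — coarse-to-fine segmentation of small lesions in 3D volumes

`csrseg` detects and segments **small lesions** (long diameter 5-30 mm) in
anisotropic 3D grayscale volumes such as liver MRI, where a single
end-to-end network reliably finds large lesions but misses small ones. It
is aimed at researchers in medical image analysis who want a fully
self-contained, CPU-runnable reference implementation of the
coarse-to-fine fusion idea, complete with a synthetic phantom benchmark and
lesion-wise, size-stratified evaluation.

The pipeline:

```
volume ──► liver segmentation (2.5D CSR-UNet)
       ──► coarse tumour segmentation (3D CSR-UNet, sliding window)
       ──► detection of candidates < 30 mm  ──► uniform 64x64x5 crops
       ──► fine segmentation of crops (2.5D CSR-UNet)
       ──► fusion: fine replaces coarse inside boxes, ∩ liver mask
```

The segmentation backbone is the **CSR-UNet**: a U-Net whose stages are
CSR blocks — dual 3x3 convolutions with batch normalisation, a
squeeze-and-excitation (SE) channel-attention module, and a residual
shortcut. Training minimises the **focal Tversky loss**

    TI = (Σ p·g + s) / (Σ p·g + α Σ p(1−g) + β Σ (1−p)g + s),
    L  = (1 − TI)^γ,        α = 0.7, β = 0.3, γ = 0.75

which generalises Dice (α = β = 0.5, γ = 1) and concentrates gradient on
small, hard foreground regions. Evaluation reports Dice, IoU, volumetric
similarity (VS), lesion-wise recall and F1, stratified by in-plane long
diameter into the clinical bins 5-10 / 10-30 / >30 mm.

Everything — including the neural networks, which run on a compact
numpy engine with explicit backward passes — works on a single CPU core
with no GPU and no external data: a built-in phantom generator produces
organ-plus-lesion volumes with exact ground truth at controlled diameters,
contrasts and noise.

## Worked example

Train the tumour stages on 30 synthetic phantoms (96x96x20 voxels,
1x1x5 mm spacing, 3-5 lesions each) and compare coarse-only versus fused
predictions on 8 held-out phantoms:

```python
from csrseg.pipeline import refinement_experiment

res = refinement_experiment(seed=1)
print(res["coarse_report"].per_bin.round(3))
print(res["fused_report"].per_bin.round(3))
```

Output from this exact call:

```
# coarse only                          # after coarse-to-fine fusion
          dice    iou     f1  recall             dice    iou     f1  recall
bin                                    bin
5-10     0.778  0.663  0.889     1.0   5-10     0.820  0.699  0.960     1.0
10-30    0.953  0.912  1.000     1.0   10-30    0.913  0.843  1.000     1.0
>30      0.977  0.956  1.000     1.0   >30      0.968  0.939  1.000     1.0
overall  0.900  0.840  0.958     1.0   overall  0.900  0.826  0.986     1.0
```

Read this as: after 20 epochs the coarse 3D network already finds every
phantom lesion (recall 1.0 in all bins — phantom contrast is clean), and
the fine stage improves the *quality* of small-lesion segmentation — Dice
for sub-10 mm lesions rises from 0.778 to 0.820 and lesion-wise F1 from
0.889 to 0.960 (fewer false-positive detections inside the crops) — while
large lesions, handled by the coarse stage alone, keep recall 1.0. On
clinical data the same mechanism is aimed primarily at recovering small
lesions the coarse stage misses outright.

A command-line interface covers the same workflow on disk
(NIfTI volumes + JSON boxes + CSV metrics):

```bash
csrseg phantom generate --n-cases 10 --seed 1 --out cohort/
csrseg train --stage coarse --config cfg.yaml --cohort cohort/ --out ckpt/
csrseg train --stage fine   --config cfg.yaml --cohort cohort/ --out ckpt/
csrseg infer --cohort cohort/ --coarse-ckpt ckpt/coarse_fold0.npz \
             --fine-ckpt ckpt/fine_fold0.npz --use-gt-liver --out pred/
csrseg evaluate --cohort cohort/ --pred pred/ --out eval/
```

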