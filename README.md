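# ctdenoise

Unpaired low-dose CT (LDCT) denoising with a cycle-consistent GAN built from
anti-aliasing components, plus a k-NN-manifold improved precision/recall
evaluator and a synthetic phantom generator so everything is exercisable
end-to-end without any dataset download.

The framework translates between two unpaired image domains (low-dose and
standard-dose CT slices) using:

- **Generator**: reflection-padded 7x7 head, encoder stages of spectrally
  normalized stride-1 convs + instance norm + LeakyReLU with blur-then-
  subsample (anti-aliased) down-sampling, a core of hierarchical feature
  synthesis (HFS) modules whose residual blocks carry concurrent spatial and
  channel squeeze-excitation (scSE) gates, decoder stages that expand
  channels and up-sample by sub-pixel (pixel-shuffle) rearrangement, and a
  sigmoid 7x7 tail.
- **Discriminators**: a bank of three patch discriminators judging realism at
  full/half/quarter input sizes (512/256/128 at training resolution), each
  with one batch-norm block, anti-aliased pooling, and a rows-only
  zero-padded 4x4 stride-1 head.
- **Losses**: probability-form adversarial loss averaged over the three
  scales, L1 cycle-consistency and identity losses, combined with weights
  lambda_adv=0.1, lambda_cyc=10.0, lambda_idt=2.0.
- **Evaluation**: improved precision/recall — each feature set's support is
  the union of k-NN hyperspheres (k=3 default); precision = fraction of
  generated features inside the real manifold, recall the converse.
  Features come from seeded random projection or summary statistics of
  ROI-restricted 128x128 patches (no pretrained weights needed offline).

Everything runs on a small NumPy reverse-mode autodiff engine included in the
package (no deep-learning framework required); `conv2d`, padding, and
normalization layers are gradient-checked against finite differences.

## CLI

```bash
# synthesize an unpaired phantom dataset (low/, std/, paired_eval/ + manifest)
ctdenoise synth --out data/ --n-low 20 --n-std 20 --size 64 --seed 0

# train (YAML config optional; defaults follow the desk-scale preset)
ctdenoise train --data-low data/low --data-std data/std --out run/ \
    --config cfg.yaml

# denoise one slice (DICOM/PNG/NPZ in or out, by extension)
ctdenoise denoise --checkpoint run/checkpoint_final.npz \
    --in data/paired_eval/low_0000.npz --out denoised.npz

# improved precision/recall between two image folders
ctdenoise evaluate --real data/std --gen run/outputs --k 3 --patches 64

# format conversion
ctdenoise convert slice.dcm slice.npz
```

The full-scale training protocol (512x512, 5000 epochs, batch 1, Adam at a
fixed 1e-4, Xavier-uniform init) is expressible through `TrainConfig`; the
desk-scale defaults keep everything CPU-sized.

## Layout

```
src/ctdenoise/
  autodiff.py        reverse-mode engine (Tensor, conv2d, pad2d, ...)
  layers.py          Module/Conv2d/norms/spectral norm/Adam/Xavier init
  ct_io.py           CTImage, min-max normalization, ROI mask, patch sampling
  dicom.py           minimal single-frame DICOM reader/writer
  phantom.py         synthetic unpaired LDCT/SDCT phantom generator
  nn_blocks.py       blur kernel/blurpool, pixel shuffle, scSE gates, HFS
  generator.py       anti-aliased encoder -> HFS core -> sub-pixel decoder
  discriminator.py   three-scale patch discriminator bank
  losses.py          adversarial / cycle / identity losses and joint loss
  trainer.py         training loop, checkpointing, denoise inference
  pr_metric.py       improved precision/recall via k-NN manifolds
  cli.py             synth / convert / train / denoise / evaluate
```
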