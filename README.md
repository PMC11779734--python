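# dfma — seedling phenotyping by segmentation and length measurement

`dfma` measures shoot and root lengths of germinating seedlings from
photographs of a germination board.  It addresses a routine bottleneck in
seed-viability and germination assays: shoot/root lengths are a key
phenotype, and measuring them by hand with a ruler does not scale to
high-throughput experiments.

The package has two stages:

1. **Semantic segmentation.**  A DeepLabv3+-style encoder–decoder (DFMA)
   labels every pixel as background, shoot, root, or seed.  The encoder is
   a FasterNet-style backbone built from *partial convolutions* (PConv): a
   3×3 convolution applied to only the first `c_p` of `c` channels, the
   rest passed through, costing `h·w·k²·c_p²` multiply–accumulates instead
   of `h·w·k²·c²`.  The stride-32 feature map is re-weighted by Efficient
   Multi-scale Attention (EMA), then passed through a series-parallel
   atrous pyramid (PSPA-ASPP) whose dilated 3×3 branches use the coprime
   rate pairs (2, 3) and (5, 7) with 128 kernels each — avoiding the
   *gridding effect* that repeated or common-divisor rates cause — plus a
   3×3 PConv branch and image-level pooling.  The decoder upsamples 8× with
   CARAFE (content-aware reassembly: a predicted, softmax-normalized
   k_up×k_up kernel per output position, shared across channels), fuses the
   stride-4 skip feature, refines with a partial-convolution block,
   classifies, and restores input resolution with a final 4× upsample.
2. **Length measurement.**  Predicted masks are thinned to one-pixel
   medial lines with Hilditch's algorithm; each seedling's shoot/root
   length is the length of the skeleton's longest geodesic path, measured
   as a subsampled polyline.  A reference coin of known diameter (25 mm by
   default), detected by Hough-gradient voting (edge pixels vote along
   their gradient direction at every candidate radius), converts pixels to
   millimetres via `mm_per_pixel = coin_mm / coin_diameter_px`.

Everything runs on the CPU: the network and its training loop are
implemented on a compact NumPy reverse-mode autodiff engine (`dfma.nn`),
and a bundled synthetic-scene generator provides images with exact
ground-truth arc lengths, masks, and coin geometry, so the whole pipeline
is testable end to end without any external dataset.

## Worked example

Generate a synthetic germination board (512×512, five seedlings, one coin)
and measure it:

```bash
python - <<'EOF'
from dfma.synthetic import SceneSpec, generate_scene
from dfma.io_datasets import write_image_png, write_mask_png
sample, truth = generate_scene(SceneSpec(seed=42))
write_image_png(sample.image, "board.png")
write_mask_png(sample.mask, "board_mask.png")
for s in truth["seedlings"]:
    print("truth %d: shoot %.1f mm  root %.1f mm"
          % (s["id"], s["shoot_len_mm"], s["root_len_mm"]))
EOF
dfma measure --mask board_mask.png --image board.png --coin-mm 25 --out lengths.csv
```

which prints (instances appear in image scan order, not generation order):

```
truth 0: shoot 20.9 mm  root 23.5 mm
truth 1: shoot 31.3 mm  root 23.8 mm
truth 2: shoot 16.5 mm  root 16.6 mm
truth 3: shoot 18.7 mm  root 19.6 mm
truth 4: shoot 20.7 mm  root 16.4 mm

 instance_id   shoot_px  shoot_mm    root_px   root_mm  seed_present  mm_per_pixel  coin_x  coin_y    coin_r
           1  90.740394 20.503499  73.152854 16.529458          True      0.225958   393.0   233.0 55.320065
           2  90.735463 20.502385 101.241723 22.876357          True      0.225958   393.0   233.0 55.320065
           3 139.704048 31.567219 105.002238 23.726074          True      0.225958   393.0   233.0 55.320065
           4  71.212701 16.091065  73.404457 16.586309          True      0.225958   393.0   233.0 55.320065
           5  82.869208 18.724944  85.919925 19.414277          True      0.225958   393.0   233.0 55.320065
```

The coin (true centre x=392.6, y=232.7, radius 55.5 px) is recovered to
sub-pixel accuracy, giving 0.2260 mm/px, and every measured length lands
within a few percent of the generator's exact arc lengths.  Across 100
random scenes the mean absolute length error is ≈2%.

Training and inference follow the same CLI (`dfma synth`, `dfma train`,
`dfma eval`, `dfma predict`), or the sklearn-style facade:

```python
from dfma import DfmaSegmenter
seg = DfmaSegmenter(width_mult=0.25, max_epochs=30, optimizer="adam",
                    lr_init=0.002, seed=1)
seg.fit(train_images, train_masks)          # lists of HxWx3 / HxW arrays
masks = seg.predict(test_images)
print(seg.score(test_images, test_masks))   # mean IoU
```

A width-reduced network trained this way on 64 synthetic 128×128 close-up
scenes reaches ~0.85 validation mIoU within 30 epochs (~2 minutes on one
CPU core).

The diagnostic `dfma gridcov --rates 2,2,2` prints the receptive-field
coverage of stacked dilated convolutions (0.2899 for three rate-2 layers —
the gridding effect; 0.6694 for the coprime pair 2,3).

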