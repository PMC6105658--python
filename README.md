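# vesseltrace

Quantitative validation tools for whole-brain vasculature imaging.

Cleared-brain light-sheet and two-photon stacks of stained blood vessels
are routinely segmented and traced to report vascular morphometry — but
real stacks come with no voxel-level ground truth, so the accuracy of the
analysis chain itself is hard to quantify. `vesseltrace` closes that loop:

* **phantoms** — synthetic capillary networks (radii 2–5 µm) grown to a
  target vascular density, rasterized on the anisotropic acquisition grid
  (0.65 × 0.65 × 2 µm by default) and rendered under either staining
  regime — whole-lumen fill (gel-albumin conjugates) or thin-wall banding
  (lectin-type markers) — with exponential depth attenuation, PSF blur and
  mixed Poisson–Gaussian noise, plus exact ground-truth masks and
  centerline graphs;
* **segmentation** — unsupervised two-class hidden Markov random field
  (Gaussian emissions, Potts prior on the 6-neighborhood, ICM inference
  interleaved with parameter re-estimation), with classical
  Otsu/isodata/mean thresholding baselines and a blockwise driver for
  stacks that do not fit in memory;
* **evaluation** — SNR-by-depth profiles (ratio of mean ROI grey values,
  sampled every 20 µm), TP/FP/FN pixel overlap against a reference mask on
  40 µm MIP slabs with precision P = TP/(TP+FP) and recall R = TP/(TP+FN),
  and perfusion-completeness classification of vessel branches;
* **tracing** — topological thinning of the mask into a centerline graph
  with spur pruning and caliber-aware cleanup, yielding 3-D segment
  lengths, total length (mm), vascular density (mm/mm³) and
  distance-transform diameters.

The segmentation energy minimized is

    E(l) = Σ_v [ (I_v − μ_{l_v})² / (2σ²_{l_v}) + ½ ln(2π σ²_{l_v}) ]
         + β · #{6-neighbor pairs with unequal labels},   l_v ∈ {0, 1}

with every inference step non-increasing in E. See `docs/methods.md` for
the full model description and parameter rationale.

## Worked example

```python
import vesseltrace as vt

# a 256-um-deep stack at light-sheet geometry with lumen staining
spec = vt.PhantomSpec.from_shape((128, 256, 256), seed=1)
phantom = vt.make_phantom(spec, vt.StainSpec(mode="lumen"))

result = vt.hmrf_segment(phantom.intensity)
counts, profiles = vt.depthwise_overlap(
    result.labels.astype(bool), phantom.mask,
    slab_um=40.0, voxel_z_um=2.0, on_mips=True, max_depth_um=240.0,
)
print(f"min slab TP rate: {min(c.tp_rate for c in counts):.2f} %")
print(f"max slab FN rate: {max(c.fn_rate for c in counts):.2f} %")

graph = vt.trace(phantom.mask, spec.voxel_um)
morph = vt.morphometry(graph, spec.volume_um3)
print(f"traced length: {morph.total_length_mm:.3f} mm, "
      f"density: {morph.density_mm_per_mm3:.0f} mm/mm3")
```

Output:

```
min slab TP rate: 99.97 %
max slab FN rate: 0.03 %
traced length: 3.152 mm, density: 445 mm/mm3
```

The phantom was grown to a target density of 450 mm/mm³ (total
3.19 mm of centerline in this 7.1·10⁻³ mm³ volume); the MRF segmentation
keeps the slab-wise true-positive rate essentially saturated down to
240 µm of depth under lumen staining, and the tracer recovers the planted
centerline length (3.19 mm) to about one percent here (within ±8% across
seeds).

A command-line interface mirrors the library:

```sh
vesseltrace phantom  --config phantom.yaml --out out/ --seed 1
vesseltrace segment  --in stack.tif --out labels.tif --method mrf --beta 1.0
vesseltrace evaluate --auto labels.tif --ref manual.tif --slab 40 --out report/
vesseltrace trace    --in labels.tif --voxel 2,0.65,0.65 --out report/
vesseltrace pipeline --config run.yaml --out report/ --seed 1
```

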