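# srclem

Correlative super-resolution light / scanning electron microscopy
(SR-CLEM) analysis of dendritic-cell podosomes.

Podosomes are micron-scale adhesion structures of myeloid cells: a dense,
protrusive actin core (~700 nm) surrounded by an adhesive ring containing
adaptor proteins such as vinculin and zyxin, embedded in a dense network of
ventral and radiating actin filaments.  Sequentially imaging the same
unroofed ventral plasma membrane by Airyscan fluorescence microscopy
(~140 nm lateral resolution) and by SEM (~2 nm pixels) puts molecular
identity and actin ultrastructure in one coordinate frame — provided the
two images can be registered to nanometre accuracy.

`srclem` implements the complete computational side of such an experiment:

* **`srclem.synthetic_data`** — seeded, ground-truth-annotated podosome
  scenes (cores, vinculin rings, zyxin caps, radiating/ventral filaments,
  interpodosomal bundles, multi-channel fiducial beads) rendered as
  4-channel LM z-stacks with a Gaussian PSF and as SEM-like ridge images
  related to the LM frame by a known affine transform.  Every downstream
  stage is testable against exact ground truth, with no external data.
* **`srclem.registration`** — sub-pixel center-of-mass localization of
  0.2 µm fiducial beads in both modalities, mutual-nearest-neighbour
  control-point matching (≥ 3 beads required), least-squares estimation of
  the SEM → LM transform, and SEM resampling onto the LM grid.  The model
  is the full 6-parameter affine

  $$\begin{pmatrix}x'\\y'\end{pmatrix} = A\begin{pmatrix}x\\y\end{pmatrix} + t,
  \qquad A \in \mathbb{R}^{2\times2},$$

  because scale + rotation + translation alone (a similarity model) cannot
  absorb the anisotropic shrinkage/shear introduced by dehydration and
  critical-point drying; alignment quality is reported as the mean
  Euclidean fiducial residual in nm.
* **`srclem.overlay`** — the figure-style merge: per-channel local
  thresholding on a radius-5 circular window (plain local mean for actin;
  Phansalkar, `t = m(1 + p e^{-qm} + k(s/r - 1))`, for vinculin and
  zyxin), foreground set to 90/255, Gaussian blur of σ = 10 px, cyan /
  green / magenta lookup tables composited additively over the SEM image.
* **`srclem.profiling`** — podosome core detection on the actin channel,
  average radial orthogonal views (a ~3 µm line through each core rotated
  in 36 steps of 10°, orthogonal slices averaged into one (r, z) image),
  x-y intensity profiles per z-section and z profiles at radial offsets of
  0 nm (core actin), 200 nm (zyxin), 360 nm (vinculin) and 1000 nm
  (network actin), min–max normalization over all z-sections, and
  mean ± SEM aggregation across podosomes.
* **`srclem.association`** — classification of *closely associated*
  podosomes (two or more actin cores enclosed by one continuous vinculin
  ring), a ridge-intensity score for the interpodosomal actin bundle on
  the registered SEM image, and event tallies with rounded percentages.
* **`srclem.cli_io`** — TIFF/CSV/JSON/YAML I/O and an end-to-end pipeline
  with a provenance manifest, exposed as the `srclem` command
  (`simulate`, `register`, `merge`, `profile`, `associate`, `run`).

## Worked example

Simulate a small cluster — three podosomes of which two form a closely
associated pair — and run the full pipeline:

```python
from srclem import synthetic_data as sd
from srclem.cli_io import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    cluster=sd.ClusterSpec(n_podosomes=3, field_size_xy=(10000.0, 10000.0),
                           associated_pairs=((0, 1),)),
    optics=sd.OpticsSpec(bead_count=5, noise_scale=1.0),
    sem=sd.SEMSpec(sem_pixel=4.0),
    seed=7,
)
manifest = run_pipeline(cfg, "out/")
r = manifest["stages"]["register"]
print(f"registration: {r['n_pairs']} bead pairs, mean residual "
      f"{r['mean_residual_nm']:.2f} nm")
a = manifest["stages"]["associate"]
print(f"association: {a['n_events']} event(s): {a['tally']}")
```

prints

```
registration: 5 bead pairs, mean residual 5.04 nm
association: 1 event(s): {'n_events': 1, 'n_with_bundle': 1, 'percent': 100}
```

The five fiducial beads were localized independently in the rendered LM
stack and SEM image and registered to a mean residual of ~5 nm — well
inside the sub-10 nm regime that makes pixel-level LM-SEM correlation
meaningful.  The associated pair was recovered from the vinculin mask as
one event, and the interpodosomal bundle was detected on the registered
SEM image (1/1 events with bundle, 100%).  `out/` also contains the
RGB overlay (`overlay.tif`), tidy per-podosome profiles (`profiles.csv`)
and the provenance manifest.

The same stages are available from the shell:

```sh
srclem simulate --seed 7 --out out/
srclem run --seed 7 --out out/
```

## Method notes

See `docs/methods.md` for the model assumptions, parameter defaults, what
the synthetic scenes do and do not emulate, and numerical choices.
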