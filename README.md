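# preful3d

Free-breathing 3D radial lung-MRI ventilation analysis on a ventilating
digital phantom: golden-means "koosh-ball" trajectory simulation, DC
self-gated respiratory binning, regularized non-Cartesian SENSE
reconstruction, phase-resolved regional-ventilation (RVent) mapping with
k-means ventilation-defect-percentage (VDP), a 60%-of-mean threshold VDP
for ventilation-weighted (Xe-style) volumes, and the regional/statistical
comparison toolkit (eight-region partition, Dice, Bland-Altman, mixed-model
correlation with Satterthwaite inference, ANOVA with Bonferroni).

All heavy numerics are built on numpy/scipy plus a self-contained
Kaiser-Bessel gridding NUFFT (numba-accelerated) and an orthonormal
Symlet-4 wavelet transform.

## Pipeline

```bash
# full pipeline on the built-in phantom (writes HDF5/NIfTI/CSV/JSON artifacts)
preful3d run --out-dir out/ --seed 7

# stage by stage
preful3d simulate --out acq.h5 --truth-dir truth/ --grid 64 --n-spokes 20000
preful3d gate acq.h5 --states 10 --share 0.3 --out bins.json
preful3d recon acq.h5 bins.json --ltv 0.01 --lwav 0.01 --out states.nii.gz
preful3d spatial states.nii.gz --auto-seeds --out-dir spatial/
preful3d preful spatial/ --out vdp.csv
preful3d xe-vdp xe.nii.gz --mask mask.nii.gz --frac 0.60 --out xe_vdp.csv
preful3d compare vdp.csv --pairs xe:preful3d --out report.json
preful3d fixtures --out-dir fixtures/
```

Stages are cached per config hash; `--force` recomputes. A single global
seed is fanned out to per-stage seeds by SHA-256 of `"<seed>:<stage>"`.

Axis convention throughout: axis 0 right-to-left, axis 1
anterior-to-posterior, axis 2 inferior-to-superior; NIfTI affines map this
to RAS+ with the stored voxel size.

## Phantom

`PhantomSpec` describes an ellipsoidal body with two ellipsoidal lungs
whose parenchymal density oscillates with a raised-cosine breathing cycle
(intensity `rho * (1 - alpha * v * b)` with tidal density fraction
`alpha = 0.3`), warped by a mass-conserving superior-inferior diaphragm
displacement. Defect spheres scale the local ventilation amplitude `v`.
The simulator renders k-space spoke by spoke through the NUFFT with
multi-coil sensitivity weighting, slow multiplicative receiver-gain drift
and complex Gaussian noise, and records per-spoke ground-truth respiratory
phase for recovery tests.

## Layout

| module | contents |
| --- | --- |
| `preful3d.trajectory` | golden-means directions, ramped radii, analytic density compensation |
| `preful3d.phantom` | phantom construction, frame rendering, k-space + Xe-volume simulation |
| `preful3d.gating` | DC extraction, Savitzky-Golay smoothing, block rescaling, quantile binning with shared spokes |
| `preful3d.nufft` / `preful3d.wavelets` | gridding NUFFT, Symlet-4 DWT |
| `preful3d.recon` | adaptive-combination coil maps, CG / monotone-FISTA SENSE with TV + wavelet penalties |
| `preful3d.spatial` | registration to mid-respiration, region-growing segmentation, 3D guided filter |
| `preful3d.preful` | phase interpolation, RVent, k-means VDP |
| `preful3d.xe` | polynomial bias correction, threshold VDP, rigid MI alignment |
| `preful3d.compare` | region partition, Dice, slab matching, Bland-Altman, REML mixed model, ANOVA |
| `preful3d.pipeline` / `preful3d.cli` | orchestration, config, console entry point |
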