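# xdsimba

Similarity-driven binning and motion-compensated compressed-sensing
reconstruction for free-running radial cardiac MRI — with a synthetic
beating, breathing phantom simulator so the whole chain can be built,
validated and studied at desk scale, without scanner data.

## The problem

Free-running whole-heart MRI acquires k-space continuously, with no ECG
triggering or breath-holds, along a 3D golden-angle radial
("kooshball") trajectory whose interleaves are punctuated by
superior–inferior (SI) self-gating readouts. All motion handling is
deferred to reconstruction. Similarity-driven binning (SIMBA) clusters
the SI projections — PCA followed by k-means on the real part of the
scores — so that each cluster collects readouts from one
motion-consistent anatomical state, and reconstructs the most populated
cluster with a fast gridded (density-compensated adjoint NUFFT)
reconstruction. That discards most of the acquired data.

This package implements the extension in which the K = 4 most populated
clusters become a dynamic dimension of a compressed-sensing
reconstruction,

    x̂ = argmin_x Σᵢ ‖F⁽ⁱ⁾ C x⁽ⁱ⁾ − y⁽ⁱ⁾‖₂² + λ Σᵢ ‖T_{u⁽ⁱ⁾} x⁽ⁱ⁾ − x⁽ⁱ⁻¹⁾‖₁ ,  x⁽⁰⁾ = x⁽ᴷ⁾,

where F⁽ⁱ⁾ is the NUFFT of cluster i's trajectory, C the coil
sensitivities, and T_{u⁽ⁱ⁾} a non-rigid warping operator estimated once
by registering adjacent clusters' gridded images. With T = identity
this is plain cyclic total variation over the cluster dimension
("XD" reconstruction); with the deformation operators it is the
motion-compensated variant ("XD-MC"), which keeps the sparsity penalty
meaningful even when adjacent clusters hold anatomically distant states
(a systolic cluster next to diastolic ones). The problem is solved by
ADMM (40 outer iterations) with 3 warm-started conjugate-gradient steps
per x-update and complex soft-thresholding in the z-update; λ = 0.3 on
data normalized so the initial gridded series peaks at 1.

The cluster-count selection, the per-cluster forward model, the warp
operator (with its exact adjoint, needed by the normal equations), the
simulator, and the image-quality metrics (blood–myocardium contrast
ratio, sigmoid-fit interface sharpness) are all part of the package.

## Worked example

`examples/motion_compensated_recon.py` runs the canonical desk-scale
study: a 64² phantom cycling through four motion states (diastole /
systole × end-expiration / inspiration, unequal dwell times), 96
interleaves of golden-angle spokes with SI self-gating, 6 coils, so the
four selected clusters land at per-cluster undersampling R ≈ 3–6 — the
published most-populated-cluster regime. Output:

```
selected k = 4, data fraction per selected cluster (%): [33.3, 27.1, 25.0, 14.6]
  NRMSE simba  = 0.1069
  NRMSE xd     = 0.1287
  NRMSE xdmc   = 0.0972
```

The similarity clustering recovers the four planted states; the plain
cluster-TV reconstruction (`xd`) is *worse* than the gridded image
(`simba`) because the systolic cluster sits next to diastolic ones and
uncompensated total variation blurs across them, while the
motion-compensated reconstruction (`xdmc`) exploits all four clusters'
data and beats both. The other examples demonstrate the clustering
(`simulate_and_cluster.py`), the registration operator
(`registration_demo.py`), and the metrics (`image_quality_metrics.py`).

A thin CLI mirrors the library for shell use:

```bash
xdsimba simulate --seed 1 --out raw.h5
xdsimba cluster raw.h5 --k-min 4 --k-max 8
xdsimba pipeline --config config.yaml --out results/
```

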