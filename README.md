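# laminmesh

Quantitative analysis of nuclear lamin meshworks in super-resolution light
microscopy images.

The nuclear lamina is a dense fibrous meshwork of lamin intermediate
filaments (isoforms A, C, B1, B2) lining the inner nuclear envelope.
Structured illumination microscopy (SIM) and single-molecule localization
microscopy (SMLM/STORM) resolve this meshwork as bright curvilinear fibers;
turning those images into numbers — how many junctions, how long the fiber
segments between them, how large the enclosed faces — is what this package
does. It is written for microscopists and image analysts working on lamins
or comparable filamentous networks.

## What it computes

**Ridge-based meshwork segmentation.** Fibers are detected with an
even-order steerable ridge filter: the order-4 detector

    k_t = −σ² ∂²G/∂v² + ¼ σ⁴ ∂⁴G/∂v⁴,    v ⟂ t,

is exactly steerable — its response at any orientation t is a fixed linear
combination of a few Gaussian-derivative basis responses, and the per-pixel
response R(t) is a trigonometric polynomial whose maximum gives the local
fiber orientation θ\*(x, y) and strength R\*(x, y). Non-maximum suppression
perpendicular to θ\* thins each fiber to its centerline; the nucleus is
masked as the area enclosed by fibers (95th/70th-percentile hysteresis +
morphology); a CDF-separation threshold splits foreground from background;
and the surviving skeleton is converted into an object-based graph of
**junctions** (single-pixel nodes), **edges** (ordered pixel paths) and
**faces** (enclosed regions). A multi-stage audit removes edges that do not
match the reconstructed image or its band-ratio (distance-weighted ratio
score, min/mean/normalized-range intensity checks, Otsu overlap, face-merge
comparison, free-standing pruning), with Otsu/Rosin automatic thresholds and
a complete removal log.

**SMLM geometric graphs.** Localization tables (x/y in nm) can be rendered
to images (binning or unit-integral Gaussians) or analyzed directly through
the Delaunay triangulation, its dual Voronoi tessellation (cell areas ≈
reciprocal local density), the Euclidean minimum spanning tree and the
nearest-neighbor graph, with the classical inclusions NNG ⊆ EMST ⊆ Delaunay.

**SIM quality control.** Widefield synthesis by phase averaging (the
equispaced phases of 1 + cos(νx + φ_p) average to 1 exactly), DC-centered
log(|FFT|+1) displays with resolution-cutoff annotation, band-ratio images,
and Rayleigh/Nyquist calculators (R_xy = 0.61λ/NA, R_z = 2ηλ/NA²).

**Synthetic phantoms.** Ground-truth meshworks (Voronoi fibers plus nucleus
rim inside an elliptical nucleus), simulated raw SIM stacks and simulated
localization scatters make every stage testable without microscope data.

## Worked example

```python
from laminmesh import synthetic, pipeline

img, truth = synthetic.make_mesh_phantom(seed=7)   # 256x256 px, 32 nm pixels
res = pipeline.segment_and_audit(img)

s = res.stats.summary()
print("junctions (deg>=3):", s["junctions"]["n"])
print("edges:", s["edges"]["n"], "| median length %.0f nm" % s["edges"]["median"])
print("faces:", s["faces"]["n"], "| median area %.2f um^2" % (s["faces"]["median"] / 1e6))
print("audit removals:", len(res.removal_log))
```

prints

```
junctions (deg>=3): 21
edges: 112 | median length 370 nm
faces: 13 | median area 2.46 um^2
audit removals: 264
```

against a phantom whose ground truth holds 15 faces and 28 junction points.
The audit removed 264 of the 376 candidate edges produced by thresholding —
mostly weak parallel side responses — leaving a meshwork whose enclosed
faces (median 2.46 µm²) are the quantity the biology cares about: lamin
isoform knockouts enlarge these faces. `res.graph` carries the full graph
(junction coordinates, pixel paths, face pixel sets) and
`res.removal_log` the per-stage audit decisions.

The same pipeline is scriptable from a shell:

```
laminmesh synth --kind mesh --seed 7 --out phantom/
laminmesh segment phantom/phantom.tif --pixel-size-nm 32 --out seg/
laminmesh audit seg/graph.json phantom/phantom.tif --mask-tiff seg/mask.tif --out audited/
laminmesh smlm localizations.csv --pixel-nm 20 --out graphs/
```

Every output directory receives a `provenance.json` with the resolved
parameters and package version.

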