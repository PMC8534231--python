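# micropat

Spatial quantification of fluorescence in micropatterned cell islands.

Cells grown on circular micropatterned adhesive islands organize their
physiology in space: mitochondrial membrane potential (ΔΨm, imaged with
TMRM) and adherens-junction markers such as E-cadherin differ
systematically between the island center and its edge. `micropat` turns
single-channel grayscale micrographs of such islands into the standard
readouts of this field:

- **Normalized radial profiles** — every pixel inside the island ROI is
  mapped to polar coordinates normalized to the centroid, r = d/R(θ) with
  r = 0 at the center and r = 1 at the edge (R(θ) is the boundary distance
  in the pixel's direction, so irregular islands still put their true edge
  at r = 1), then binned into a mean-intensity curve I(r).
- **Center/edge region means and fold change** — n square sampling ROIs
  (default 5) placed at r = 0.1 and r = 0.85; fold change
  (Ī_edge − b)/(Ī_center − b) with optional background b.
- **Cell–cell contact index** — for two traced cell contours, the ratio of
  overlap to combined area, area(A∩B)/area(A∪B), by exact polygon
  clipping; 0 = disjoint, 1 = identical.
- **Cell density** — ITCN-style counting: difference-of-Gaussians band-pass
  at the expected cell diameter, then well-separated local maxima.
- **Junction line scans** — width-averaged intensity profiles across
  intercellular junctions, aligned at the junction and averaged over pairs.
- **Junction-marker area per cell** — above-threshold marker pixels within
  a band around each cell's boundary.

A synthetic micropattern generator (`micropat.simulate`) renders islands
with planted radial gradients, cell blobs, Voronoi-tessellation junction
ridges and Poisson–Gaussian camera noise, together with the exact ground
truth — so the whole measurement chain is testable without any microscope
data.

## Worked example

Generate a synthetic island whose edge:center ΔΨm-like contrast is planted
at ~3-fold (edge-high sigmoid, Poisson peak SNR 20), then run the full
measurement chain:

```python
import micropat as mp

spec = mp.SyntheticSpec(seed=1, noise=mp.NoiseModel(poisson=True))
img, truth = mp.generate(spec)

roi = mp.detect_island(img)
bg = mp.estimate_background(img, roi)
prof = mp.radial_profile(mp.to_polar(img, roi), n_bins=50, normalization="max")
center = mp.quantify_regions(img, mp.place_region_rois(roi, "center"), "center")
edge = mp.quantify_regions(img, mp.place_region_rois(roi, "edge"), "edge")
fc = mp.fold_change(edge, center, background=bg)
```

This prints, via the obvious f-strings:

```
detected: circle, centroid=(255.50, 255.50), radius=200.0 px
background (median outside): 10.0
profile at r=0.05: 0.350   at r=0.95: 0.999
center mean: 143.1   edge mean: 408.7
fold change (edge/center, background-corrected): 2.99
planted fold change: 2.99
```

The detected ROI recovers the planted disc (center (255.5, 255.5), radius
200 px) exactly; the max-normalized radial profile rises from 0.35 at the
center to ~1.0 at the edge; and the background-corrected edge/center fold
change of 2.99 recovers the planted 3-fold contrast through the complete
detect → polar-map → place-ROIs → quantify pipeline despite shot noise.

## Command line

```sh
micropat simulate --out island.tif --truth truth.json --seed 1
micropat profile island.tif --out results/
micropat regions island.tif --out results/
micropat contact island.tif --contours cells.json --out results/
micropat run --config analysis.yaml        # multi-stage run with manifest
micropat compare run1/manifest.json run2/manifest.json \
    --metric fold_change --labels confined,unconfined --out compare.csv
```

Every stage writes a CSV; `run` additionally writes a JSON manifest
(config, config hash, input checksums, output paths) and is byte-for-byte
reproducible: the same inputs and config always produce identical files.
Contours are a transparent JSON format
(`[{"id": ..., "vertices": [[x, y], ...]}]`, pixel coordinates); images
are single-plane 8/16-bit grayscale TIFFs.

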