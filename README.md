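# trichrome

Analysis toolkit for trichromatic (three-colour) serial two-photon
microscopy of combinatorially labelled brain tissue.  Simultaneous
excitation of three spectrally distinct fluorescent proteins — Brainbow-style
stochastic labels or three separately injected anterograde tracers — yields
terabyte-scale mosaics in which the *colour ratio* of every structure
carries identity.  Extracting that identity takes a specific computational
chain, which this package implements and tests end to end:

* **`trichrome.tiles`** — tile edge cropping, flat-field correction from
  tile-averaged illumination profiles, translation-only mosaic stitching by
  normalised cross-correlation;
* **`trichrome.unmixing`** — linear spectral unmixing.  Raw channels are a
  unit-diagonal mixture of the true intensities,
  `raw = M · corrected` with `M = [[1, a_GR, a_BR], [a_RG, 1, a_BG],
  [a_RB, a_GB, 1]]`; the six bleed-through coefficients `a_XY` are estimated
  from reference ROIs (max-intensity or per-tracer barycentres projected to
  the ternary-diagram corners) and the system inverted per pixel.  Ternary
  and hue–saturation coordinates, and colour-mode counting;
* **`trichrome.chromatic`** — chromatic-shift metrology from nanocrystal
  centroid pairs: affine fits of the lateral shifts (ΔX, ΔY), a radial
  polynomial for ΔZ(ρ), magnitude maps of √(ΔX²+ΔY²), and a sub-field
  quality flag (< 0.6 µm over 350 µm);
* **`trichrome.projection`** — multiplexed projection mapping: square-root +
  histogram-matching enhancement, exact multi-Otsu segmentation with
  connected-component filtering, colour-exclusive masks, per-super-pixel
  (30×30 px) projection-strength, confidence, and interdigitation maps,
  and classification of each super-pixel as single / dual / triple
  projection by nearest of seven RGB reference points;
* **`trichrome.interfaces`** — astrocyte–astrocyte interface geometry: the
  Voronoi plane of a soma pair as null model, the bias parameter (% of
  interface points on the far side), the orientation parameter (angle to
  the Voronoi plane, orthogonal plane fit), and biharmonic (thin-plate)
  relief maps;
* **`trichrome.morphometry`** — colour-cluster construction (connected
  same-colour contact components) and contacts-per-astrocyte accounting
  with per-layer summaries;
* **`trichrome.phantom`** — synthetic multicolor phantoms with exact ground
  truth for every stage: filamentous axon populations with controllable
  pixel overlap, Voronoi astrocyte territories with engulfed dark somata,
  vignetted tile grids, bead fields under a known shift model, planar
  interfaces, and colour-combination clouds.

The science behind each stage and all parameter defaults are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Generate a tricolour axon phantom, corrupt it with a known bleed-through
model and detector noise, re-estimate the model from single-population
ROIs, unmix, and quantify interdigitation:

```python
import numpy as np
from trichrome import phantom
from trichrome.unmixing import (MixingModel, RoiColorSample,
                                estimate_mixing_model, unmix)
from trichrome.projection import quantify_projections, region_proportions

true_model = MixingModel(a_RG=0.18, a_GR=0.07, a_GB=0.12, a_BG=0.05)
image, truth = phantom.generate_projection_phantom(
    shape=(900, 900), n_per_population=(12, 12, 12),
    overlap_fraction=0.2, seed=5)
raw = phantom.apply_mixing_and_noise(image, true_model, gain=200.0,
                                     read_noise_sd=0.02, seed=6)

samples = []
for c, pop in enumerate("RGB"):
    solo = truth.axon_membership[c] & \
        ~np.delete(truth.axon_membership, c, axis=0).any(axis=0)
    idx = np.argwhere(solo)[:200]
    vals = raw.data[:, idx[:, 0], idx[:, 1]].mean(axis=1)
    samples.append(RoiColorSample(tuple(vals), population=pop))
est = estimate_mixing_model(samples, mode="barycentre")
print({k: round(v, 3) for k, v in est.to_dict().items()})

corrected = unmix(raw, est)
result = quantify_projections(corrected, block_px=30, n_classes=2)
print(region_proportions(result.interdigitation.classes).round(3))
```

Output:

```
{'a_GR': 0.072, 'a_BR': 0.007, 'a_RG': 0.178, 'a_BG': 0.047,
 'a_RB': 0.009, 'a_GB': 0.123}
R      0.224
G      0.211
B      0.158
RG     0.111
GB     0.144
RB     0.123
RGB    0.029
```

The estimated coefficients match the generating model (0.18 → 0.178,
0.07 → 0.072, 0.12 → 0.123, 0.05 → 0.047; the true-zero coefficients come
back below 0.01), and the class proportions say that ~59% of
signal-bearing 24 µm super-pixels contain a single axon population, ~38%
two interdigitated populations, and ~3% all three — the phantom was
generated with 20% pixel-level overlap, so substantial dual mixing is
expected.  The mean confidence (exclusive over total signal) across
super-pixels is 0.582, flagging how much evidence the exclusivity step
discards at this overlap level.

## Command line

The same stages are exposed as subcommands of a single CLI, driven by one
YAML config with per-stage sections (unknown keys are rejected; every run
writes its resolved config and a JSON-lines provenance record next to the
outputs):

```
trichrome simulate      --config run.yml --out sim/
trichrome preprocess    --config run.yml --tiles-dir sim/tiles --out mosaic/
trichrome unmix         --image mosaic/mosaic.tif --model model.json --out unmixed/
trichrome chromatic-fit --beads sim/beads.csv --out shift/
trichrome project-map   --image unmixed/unmixed.tif --block-px 30 --out maps/
trichrome interface     --points pair.csv --out iface/
trichrome morphometry   --astrocytes cells.csv --adjacency contacts.csv --out morpho/
```

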