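# Methods

## Detection model

Tubercle counting is a five-step, fully deterministic pipeline per image:
scale calibration → crop → RGB-to-HSB conversion → inclusive band threshold
→ hole filling → connected-component analysis with a physical size filter.
The underlying assumptions are those of the rhizotron imaging setup it
serves: tubercles are the only strongly saturated orange objects in the
cropped field of view, roots and background paper are near-white (low
saturation), and the image scale is uniform (flat rhizotron, fronto-parallel
camera), so one px/mm factor converts pixel areas to mm².

Conventions where the classic recipe leaves room:

- **HSB byte mapping.** Hue in degrees maps to bytes as round(deg·255/360);
  saturation and brightness as round(fraction·255). Achromatic pixels get
  hue 0. Band endpoints are inclusive on all six bounds. No attempt is made
  at bit parity with any particular desktop tool's converter; conversions
  agree with the standard hexcone formulas within ±1 byte (tested against
  `colorsys`), and the default band is wide enough that ±1 at the edges is
  immaterial.
- **Connectivity.** Foreground components are 8-connected, background
  4-connected (the standard duality). Diagonally touching blobs therefore
  merge — which reproduces the documented under-count of very close
  tubercles.
- **Order of operations.** Holes are filled *before* the size filter, so a
  ring-shaped detection is measured at its filled area.
- **Size bounds** (default 0.05–20 mm²) are inclusive at both ends; "between
  0.05 and 20 mm²" is ambiguous and inclusivity is the simpler contract.
- **Hue wraparound** is supported (`h_min > h_max` passes through 255→0) so
  red-centered bands remain expressible, although the default band does not
  wrap.
- **Centroids** are binary (unweighted) centers of mass in pixel-index
  coordinates, reported in mm relative to the crop origin and in
  original-image pixels. Particle ids are assigned in raster order of each
  component's first pixel, so outputs are byte-stable across runs.
- **Corrections.** A delete point removes the particle whose bounding box
  contains it (nearest centroid among several hits), falling back to the
  nearest centroid within 2 mm; particle tables round-trip through CSV and
  do not retain region masks, so the bounding box stands in for exact region
  membership. Added particles are count corrections only: class
  `manual_added`, zero measured area.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `px_per_mm` | 22 | scale; 1100 px ruler line = 50 mm |
| crop | (400, 426, 2634, 1824) | region of interest in the 3280×2464 reference frame |
| tubercle band | H 0–55, S 102–255, B 95–255 | 8-bit HSB range isolating orange tubercles |
| size filter | 0.05–20 mm² | rejects specks and large non-tubercle regions |
| match tolerance | 2 mm | one-to-one centroid matching radius, ≈ one tubercle radius |

The band and size defaults are the values used for the reference screen and
transfer unchanged to the synthetic canvas, which equals the reference crop.

## Evaluation statistics

Count-level agreement is the Pearson product-moment correlation of
(reference, automatic) per-image counts plus the least-squares slope through
the origin b = Σxy/Σx². Degenerate inputs (fewer than two images, constant
counts, Σx² = 0) yield NaN/null, never a zero-division. Object-level
matching is greedy nearest-first on centroid distance with ties broken by
(auto id, truth id); greedy matching is deterministic and O(n² log n), which
is adequate at ≤ ~100 objects per image, and differs from optimal assignment
only in contrived geometries. Per-image recall/precision are averaged with
the sample standard deviation (ddof = 1); undefined ratios (no truth / no
detections) are excluded with the effective n reported. The visual criterion
by which a human pairs a manual mark with an automatic particle has no
published definition, so the distance rule is a labeled stand-in in every
report.

## Synthetic scenes

The generator emulates the rhizotron imaging conditions well enough to
exercise every documented behavior of the detector, with exact ground truth:

- near-white noisy paper background and low-saturation cream roots drawn as
  random-walk polylines (never above the saturation cut);
- tubercles as soft-edged ellipses anchored on roots, equivalent radius
  uniform in 0.15–2.5 mm (areas ≈ 0.07–19.6 mm², inside the size filter);
  colors drawn inside the band with margin (H 5–40, S 150–255, B 110–240),
  so every clean tubercle is detectable by construction;
- **pale** tubercles with S ~ U(30, 95): miss the saturation cut;
- **necrotic** tubercles with B ~ U(30, 90): miss the brightness cut. They
  are rendered with a dark rim (B ≤ 45) because a dark saturated core
  blended directly toward the white background would cross a thin ring of
  intermediate color that the band accepts; the rim keeps every blend path
  out of band so necrotic tubercles fail for the documented reason;
- **clusters**: a member is placed at 0.75 × (r₁+r₂) from its anchor so the
  two masks touch and merge into one particle. `cluster_frac` is the
  expected fraction of tubercles that are members of a touching pair;
- **distractors** (rockwool speckles, stem-base blob) in the top strip of
  the canvas, colored inside the band and sized inside the filter, absent
  from the ground truth — each one a false positive.

The soft edge is a 1.2 px linear alpha ramp centered on the nominal
boundary, so the thresholded footprint tracks the nominal ellipse within
about ±0.25 px; with the radius range above, rendered areas stay strictly
inside the size filter. Non-cluster placements keep a clearance of 1.14 ×
(r₁+r₂) + 4 px between centers (1.14 covers the worst-case semi-major axis
at the minimum aspect ratio 0.78), so clean scenes never merge.

Rendering is deterministic given the scene seed. Experiment designs draw
per-image counts from per-scenario distributions (truncated normal rounded
to int for susceptible-like scenarios, matching mean ± sd phrasing; uniform
integers; exact 0 for resistant) using the master seed, and each image
renders from a child seed derived from (master seed, image index), so
appending scenarios never perturbs earlier images.

What the generator does **not** model: real root architecture, lighting
gradients and vignetting, camera noise structure, JPEG artifacts, tubercle
shape irregularity, necrotic-progression dynamics, and the true (unpublished)
color distributions of tubercles across genotypes — the color model is an
assumption chosen to straddle the published band edges. Passing the
synthetic benchmarks therefore shows that the implementation is faithful and
self-consistent (and that the documented failure modes have the documented
consequences); it does not certify accuracy on real images, for which the
band would be re-tuned on a few representative frames as in any screen.

## Benchmark problem sizes

The acceptance benchmarks use full-size canvases (2634 × 1824 px at
22 px/mm): 19 images with true counts uniform in 10–80 and all confounds
enabled (5 % pale, 8 % cluster members, 2 distractor blobs/image), and a
4-scenario experiment of 20 images (susceptible ≈ 45 ± 6, intermediate
≈ 15 ± 5, tolerant < 5, resistant 0). Unit and property tests use a
600 × 450 px canvas with proportionally fewer, smaller tubercles; the
pipeline is scale-calibrated, so behavior is identical up to the px/mm
factor (verified by the upsampling-invariance test).

## Known limitations

- Greedy matching can differ from optimal assignment when detections are
  denser than the 2 mm tolerance.
- A merged touching pair yields one detection that matches only one of its
  two ground-truth members; the other is counted as missed, which is the
  honest accounting of the under-count.
- The semiautomatic delete rule uses bounding boxes, not exact region
  membership (see above); for overlapping elongated particles a click near a
  shared edge may delete the neighbor with the closer centroid.
- RGBA inputs are rejected unless alpha dropping is explicitly requested;
  grayscale images are always rejected — the method is inherently chromatic.
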