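# Methods

## Scope and model

`fish3d` scores break-apart FISH probes in confocal z-stacks. The model of
the specimen is deliberately minimal: a field of ellipsoidal,
DAPI-counterstained nuclei, each containing a small number of point-like
gene signals (FITC and TRITC), imaged as an L-layer z-stack with isotropic
XY sampling (default 0.16 μm/pixel) and coarser axial sampling (default
0.6 μm between layers, L = 7). All decisions are made in μm space so the
anisotropy of the voxel grid is explicit rather than implicit.

Three constants drive the scoring and are exposed in `RunConfig`:

| parameter | default | meaning |
|---|---|---|
| `spot_diameter_um` | 0.6 | apparent diameter of one gene signal |
| `breakapart_cutoff_um` | 1.2 | 3D distance at or above which a FITC–TRITC pair is a break-apart (defined as twice or more the spot diameter, so the boundary itself is break-apart) |
| `abnormal_fraction_cutoff` | 10.0 % | largest break-apart nucleus fraction still diagnosed negative |

## Preprocessing

Per layer and channel, a separable Gaussian low-pass with a unit-sum kernel
built from exp(−(x−μ)²/(2σ²)) (σ in pixels, default 1.0; μ fixed at 0;
reflect boundaries; σ = 0 is the identity). Grayscale opening and closing
(flat disk, radius 2 px by default) follow — but only on DAPI. The gene
signals are at the resolution limit (~4 px across), and an opening with any
useful element radius erases them, so FITC/TRITC get the Gaussian only.
Morphology runs on intensity images (grayscale min/max definitions), not on
thresholded masks; binary inputs behave as the set definitions.

## Nucleus segmentation

Segmentation is template matching against a parametric bank of filled
ellipses. Six score functions are implemented (SD, NSD, C, NC, CC, NcC, all
by their direct-summation definitions, evaluated with FFT-accelerated
window sums). The default is NcC — the Pearson correlation of the
mean-subtracted template with each mean-subtracted window — because it is
invariant to stain intensity offset and gain. Degenerate windows (zero
variance under a normalized score) receive the method's worst value (NSD 2,
NC 0, NcC −1) instead of dividing by zero.

The default bank spans semi-major radii 2–8 μm in 1 μm steps, aspect
ratios {1.0, 1.3} and 30° orientation steps (49 templates). A denser grid
(0.5 μm radii, aspects to 1.5, 15° steps) measurably changes nothing on
synthetic nuclei while costing ~3× the runtime, because NcC is insensitive
to moderate shape mismatch; the grid is fully configurable
(`template_radii_um`, `template_aspects`, `template_orientation_step_deg`),
and a directory of user-supplied template images overrides it. The 2 μm
lower radius matters: off-equator cross-sections of a 4 μm nucleus are
small, and without small templates the top and bottom layers go unmatched.

Peaks with NcC ≥ `match_threshold` (default 0.6) compete in greedy
non-maximum suppression: footprints overlapping an already-accepted
footprint by more than 30% (intersection over the smaller) are suppressed.
Accepted footprints, intersected with the layer's Otsu foreground, form the
layer mask. 8-connected components below `min_component_size` (default: the
area of a 2 μm-radius disk) are erased as isolated vertices. Components on
adjacent layers merge into one 3D nucleus when intersection over the
smaller area exceeds 0.5.

QC then discards nuclei that are not clear individuals: any mask pixel on
the image border; overlap of two nuclei's z projections; volume outside
`nucleus_volume_bounds` (unbounded by default); or contested area — during
suppression, a passing peak whose center lies outside every accepted
footprint and more than 1 μm from every accepted peak marks its footprint
as contested, the signature of a second nucleus competing for the region.
Discarded nuclei are counted in the report but never scored.

**Known limitation.** Two nuclei touching in-plane with featureless DAPI
interiors merge into one mask component and can segment as a single larger
"clear" nucleus; with no intensity valley there is nothing to split on, and
watershed splitting is out of scope. The overlap QC reliably catches
axially stacked nuclei (distinct components on non-adjacent layers with
overlapping projections) and peak-contested regions.

## Spot detection

Within a clear nucleus, a voxel is a candidate when its intensity is
maximal over the up-to-24 in-plane neighbors (5×5 window minus center,
restricted to the nucleus mask — hence "up to") **and** exceeds a floor of
mean + k·SD (k = `intensity_floor_k`, default 3) over all in-nucleus voxels
of that channel. The floor exists because a pure local-maximum rule fires
on every background ripple; k = 3 keeps the uniform interior silent while
passing any rendered signal, whose peak sits far above the in-nucleus
spread. Plateau ties all become candidates. Candidates within one spot
diameter of each other in μm (single linkage, across layers) are one
physical signal; the group keeps its maximum-intensity member, ties broken
by lowest (layer, row, column). Pixel→μm conversion happens exactly once,
at Spot construction.

## Pairing and classification

All FITC–TRITC distances within a nucleus form a weighted bipartite
network. Selection is greedy by ascending 3D distance with non-repetitive
signals, ties broken by spot ids (so results are independent of input
order). Greedy — not minimum-total assignment — is the scoring rule; the
optimal-assignment variant exists only as a test oracle, and the two agree
whenever closest pairs are mutually nearest. The greedy prune always
exhausts the smaller channel, so pair count = min(|FITC|, |TRITC|).

A break-apart-called pair contributes one split FITC and one split TRITC
signal to the nucleus's (C, G, R) triple; classification is the total
function described in the README. Two choices deserve note:

* the 1.2 μm boundary maps to break-apart (the cutoff is "twice **or
  more**" the spot diameter);
* "other" patterns (split signals of one color only, lone fusions, …) are
  reported but do **not** count toward the 10% abnormal fraction by
  default, because the diagnosis hinges on rearrangement patterns;
  `abnormal_includes_other` flips this.

A nucleus with zero signals is dropped from counting. A case with zero
counted nuclei raises an explicit error rather than fabricating a
diagnosis. `remove_nucleus` moves one nucleus to discarded and recomputes
every ratio; it is idempotent.

## Synthetic data generator

`SynthParams`/`generate_case` emulate the target acquisition: default
256×256 px (~41 μm) fields, 7 layers × 0.6 μm, 0.16 μm/pixel, 4 nuclei of
semi-major radius 3–4.5 μm (aspect ≤ 1.3, axial semi-axis ≤ 1.3 μm, flat
interior intensity), spots as isotropic Gaussian blobs with σ = 0.3 μm so
the rendered signal has the assay's ~0.6 μm apparent diameter. Noise is
off by default; gaussian and poisson models are available. The default
pattern mix is a clinically negative-looking case (85% normal, 5% multiple
copy, 2.5% + 2.5% break patterns, 5% other); studies that need a specific
composition set `pattern_mix` explicitly.

Placement rules keep ground truth unambiguous relative to the 1.2 μm
decision boundary: co-localized partners ≤ 0.6 μm apart, designated
break-apart partners 1.8–3.6 μm apart, distinct signal sites ≥ 2 μm apart,
all spots within 0.7× the nucleus ellipsoid, nuclei non-overlapping with
≥ 2 μm clearance (an `overlap_pair` flag deliberately builds one axially
stacked, projection-overlapping pair for QC tests). Spot centers are
quantized to the voxel grid: the detector reports peak voxels, not
sub-voxel fits, so grid-aligned truth tests method error rather than
quantization error. Boundary behavior of the cutoff is tested separately
with exact-geometry fixtures. `expected_pairs` are produced by running the
greedy matcher on the true coordinates — legitimate because the separation
bands make the intended pairing the unique greedy outcome — while pattern
labels and the expected diagnosis are assigned by construction, independent
of the classifier.

What the generator does **not** emulate: optics beyond a Gaussian PSF (no
Airy rings, no depth-dependent aberration), chromatic shift, DAPI texture,
autofluorescence, sectioning truncation of nuclei, or densely packed
tissue. Passing the recovery suite therefore demonstrates the scoring
logic is correct on well-formed input; it does not certify segmentation
performance on real slides.

## Numerical and determinism notes

* Matching scores agree with naive direct summation to ≤ 1e−9 relative
  error; window variances are clamped at zero before square roots.
* All internal arithmetic is float64; 8- and 16-bit unsigned TIFF input is
  accepted.
* Component labels are assigned in raster order of each component's first
  pixel; nucleus ids in raster order of first appearance — every ordering
  in the pipeline has a deterministic tie-break, so repeated runs are
  byte-identical and input permutations cannot change results.
* The only randomness is the synthetic generator's `numpy` Generator,
  seeded from `SynthParams.seed`.

## Problem sizes used in the shipped checks

The recovery suite runs 20 seeded noise-free cases at the default field
size (4 nuclei each); the diagnosis sweep uses 100-nucleus cases at
abnormal fractions 0–30% in 1% steps; the cutoff sweep uses separations
0.1–2.0 μm in 0.1 μm steps; oracle-equivalence checks use 100 random
matching instances (all six methods) and 200 random pairing instances with
up to 6 spots per channel.
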