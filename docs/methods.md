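# Methods

This note documents the models, conventions and design choices behind
`pixelplex`, in the order data flows through the pipeline.

## Coordinate and intensity conventions

Images are `[row, col]` arrays, 0-based, pixel centers at integer
coordinates, row = y increasing downward.  Physical position of pixel
`(r, c)` is `(r·s, c·s)` µm for pixel size `s`.  Fluorescent channels
are 16-bit at 0.3 µm/px, chromogenic channels 8-bit at 0.5 µm/px,
matching the acquisition hardware classes the package targets.  All
output tables carry explicit units in their column names (µm, px,
fraction vs percent), because density and class quantities are easy to
confuse across the two scales.

## Marker masks and pixel classes

Thresholding is strict (`I > t`): the comparison operator is a genuine
free choice, and the strict form makes the degenerate case (image
everywhere equal to the threshold) yield an empty mask, which is the
conservative reading.  Automatic thresholding (Otsu) refuses constant
images rather than inventing a cut.

The small-group filter removes connected components of fewer than 9
pixels (8-connectivity by default — thin stellate processes are
visually contiguous along diagonals; 4-connectivity is available in
`ThresholdSpec`).  It is applied exactly once, per antibody mask,
after thresholding and before any union or intersection, so that all
downstream counts refer to one consistent set of masks; derived class
masks are not re-filtered.

The MC&M reference mask is the union of CD68, CD163, CD11b and CD11c
only.  CD206 also stains vessel endothelium, so CD206 signal is
interpretable only underneath the myeloid compartment; it is
intersected with the reference (`restrict_cd206`) before class
decomposition.  This also requires the reference itself to be
CD206-independent, which is why CD206 is not part of the union.  A
consequence worth noting: within the reference, a CD206-only single
class cannot occur.

Class decomposition encodes each pixel's marker pattern as a 5-bit
code and histograms the codes over the reference support; the exclusive
single/double/triple/`P4,5` classes partition the reference exactly (an
invariant the test suite checks against a per-pixel brute-force
enumeration).  Percentages with an empty reference are reported as
missing (NaN), never as zero, and case-level averages (unweighted mean,
sample n−1 standard deviation) drop missing tiles and decrement their
class's tile count.

## Nuclear phenotyping

Segmentation recipe: Gaussian smoothing (σ = 1 px) → global threshold
(Otsu default) → hole filling → distance-transform watershed with
peak markers (minimum peak separation 5 px) → minimum-area filter
(20 px).  This is deliberately standard; it is adequate for counterstain
images dominated by convex nuclei and is fully configurable through
`SegmentationSpec`.

The doughnut width is round-half-up of (⅓ × tile mean nuclear radius),
with a hard error when it rounds to zero — a silent zero-width ring
would make every density 0/0.  Doughnuts exclude the pixels of *all*
nuclei and are clipped at tile borders; rings of neighboring cells may
overlap, since each cell is classified independently and ownership
resolution would add an arbitrary tie-break with no measurable benefit.
Positivity is strict (`density > threshold`, default 0.1), so threshold
0 means "any positive pixel in the ring".

## Co-registration

The transform maps chromogenic-space µm points to fluorescent-space µm
points; both pixel sizes ride along as metadata, so a mask crosses
geometries in exactly one nearest-neighbor resampling (bilinear for
intensities).  Estimation maximizes normalized cross-correlation of the
Gaussian-smoothed counterstains (σ = 0.9 µm on both sides) over six
affine parameters (rotation, two translations, two log-scales, shear).
The search is deterministic: a fixed grid of candidate rotations (−10°
to 10°, step 2.5°), each given a phase-correlation translation
initialization, then Powell refinement of the best candidate.  An
optimum whose NCC stays below a configurable floor (default 0.2) raises
a registration error; there is no silent fallback.  On synthetic pairs
(0.5 → 0.3 µm/px, rotations to 10°, translations to 20 px, ≥ 100
nuclei) the recovered transform lands within ~0.02 µm mean corner
displacement of the truth, comfortably inside the one-IF-pixel (0.3 µm)
acceptance radius.

Per-tile estimation is the default; a per-case mode reuses the first
tile's transform for the remaining tiles of the case, for workflows
where the stage was aligned once per slide.

## Spatial statistics

Densities are `|class ∩ region| / |region|` with empty regions reported
as missing.  Stroma is tissue minus tumor, where tissue is the
co-registered (covered) area of the transferred mask.  The tumor:stroma
ratio is undefined when the stroma holds no class pixels.

Border nuclei are those whose centroid pixel lies inside the tumor mask
at an inward Euclidean distance ≤ the band width (default 10 µm,
config-exposed and echoed in output metadata — the appropriate offset
is a study-level choice, not something the package can infer).  The
inward distance is computed on an edge-replicated padding of the tumor
mask, so a tumor cropped by the tile boundary does not acquire an
artificial border along that edge; a tumor filling the whole tile has
no border at all.

Nearest-class distances sample the Euclidean distance transform of the
mask complement (in µm) at the nucleus centroid rounded to its pixel
center.  The centroid was chosen as the reference point over the
nuclear edge because it is stable under small segmentation changes.  An
empty class mask yields a missing value — not zero and not infinity —
and missing values are dropped (but counted) from histograms.
Histograms use an exact-contact bin {0} followed by half-open bins with
inclusive upper edges, so d = 20 µm falls in (0,20].

## The synthetic-tissue simulator

The simulator generates what the analysis assumes: compact round T
cells (all CD3 signal perinuclear), stellate macrophages (3–6 polyline
processes by default, 10–40 µm long, 1–2 px wide, drawn as jittered
three-segment walks from the nuclear rim), compact myeloid cells,
contiguous tumor-epithelium regions (random ellipses targeting a
configurable area fraction), per-cell-type marker co-expression
probabilities (independent Bernoulli draws), and the chromogenic
rendition produced through a known affine motion and pixel-size change.
Intensities follow a two-level background/signal model (300/20 000 for
16-bit fluorescent channels, 15/200 for 8-bit chromogenic ones) with
additive Gaussian noise (σ = 400 and 6), clipped to the dtype range —
the simplest model that exercises thresholding.

Placement is rejection sampling with a minimum centroid separation of
1.5 × the sum of the two nuclear radii, so nuclei are disjoint by
default and the number of DAPI connected components equals the number
of simulated cells.  A `tumor_border` placement mode accepts stroma
positions with probability `exp(−d/L)` for distance d to the tumor
mask and decay length L, reproducing border-seeking infiltration
patterns.  Randomness is split into independent seeded streams (tumor
geometry, radii, placement, marker draws, process morphology, noise),
so changing only the morphology of a cell type leaves layouts
untouched — this is what makes matched compact-vs-stellate comparisons
possible.  The same `(config, seed)` always produces bit-identical
tiles.

Two `MorphologySpec` fields emulate thin physical sectioning of large
stellate cells: with `nucleus_out_of_section_prob` the cell's footprint
is rendered without its nucleus, with `soma_out_of_section_prob` the
nucleus is rendered but the marker signal is reduced to the processes.
Both default to 0 (preserving the nuclei-conservation invariant) and
are switched on only in the stellate study scenario below.

What the simulator does *not* model: optical point-spread, spectral
bleed-through and autofluorescence (emission filters make channels
independent), vessel CD206 staining, intensity gradients, and
whole-slide mosaics.  Tests passing on synthetic tiles therefore
demonstrate the correctness of the measurement path — mask algebra,
geometry, registration, distances — not robustness to real-world
staining artifacts, which would need annotated tissue.

## Reference study conditions

The seeded studies in `pixelplex.experiments` (shared by the test suite
and `scripts/acceptance.py`) fix the following conditions:

* **Affine recovery** — 20 pairs, 384×384 IF tiles, 120 compact nuclei
  (radius 2.5 ± 0.3 µm), rotations uniform in ±10°, translation
  components uniform in ±4 µm (≤ ~19 IF px), defaults elsewhere.
  Success = mean corner displacement ≤ 0.3 µm.
* **Class proportions** — 10 seeds, 60 myeloid cells per 512×512 tile,
  P(CD68) = 1, P(CD163) = 0.3 independent; expectation 70%/30% for the
  CD68-single and CD68/CD163-double classes.  The residual deviation
  (≲ 2 points) comes from footprint-area variance across cells and
  occasional footprint overlap between cells of different classes.
* **Morphology correlation** — 28 matched tile layouts emulating fields
  of one tissue region: cell counts uniform in {20…40} (cellularity
  varies moderately within one region), per-tile process counts uniform
  in {0…8} (process elaboration varies strongly), process length
  12–18 µm ≈ 5 × the 3 µm nuclear radius, and sectioning probabilities
  0.35/0.35 for the stellate arm — roughly one macrophage in three
  contributes signal without its nucleus, plausible for cells spanning
  several section thicknesses.  The compact arm uses the same layouts
  with perinuclear signal only.
* **Spatial ordering** — 20 runs; CD68/CD163⁺ macrophages placed with a
  10 µm border decay, CD11b/CD11c⁺ myeloid cells with 60 µm; uniformly
  placed T cells provide nuclei, and distances are measured from
  tumor-border nuclei (10 µm band) to each thresholded marker mask.
* **Uniform density** — 10 tiles of 400 small (0.8 µm) CD68⁺ cells
  placed uniformly; pooled over tiles (> 200 000 class pixels) the
  tumor:stroma ratio is expected at 1.  A ~1–3% upward bias is possible
  because the placement margin slightly depletes the stroma near tile
  edges.

## Known limitations

* The nuclear segmenter is tuned for convex, well-separated nuclei; it
  will merge dense clusters that a learned segmenter would split.
* Registration assumes the two renditions overlap substantially
  (≥ 25% by default) and share nuclear content; it does not handle
  deformable distortion or whole-slide alignment.
* Tumor masks derived by thresholding cytokeratin channels stand in
  for operator-trained tissue classification; on real material the
  mask quality bounds every downstream density and distance.
* Class percentages near zero are noisy at small reference masks; the
  case aggregation reports per-class tile counts so that such classes
  can be judged on their support.
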