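# Methods

`granulequant` quantifies two kinds of fluorescence-microscopy data from
P-body (PB) biology: widefield fields of budding-yeast cells carrying
GFP/mCherry-tagged PB components, and confocal fields of in vitro
phase-separated protein droplets. Because no raw imaging data accompany
the study it re-implements, every claim the package makes about itself is
a *recovery* property: a seeded generator plants a scene with known
parameters, the pipeline runs blind, and the estimate is compared with the
planted truth.

## Cell segmentation by edge-normal voting

Yeast cytoplasmic fluorescence makes cell interiors bright on a dark
background. Segmentation proceeds in four steps.

1. **Edges.** Zero-crossings of a Laplacian-of-Gaussian response
   (`edge_sigma_px`, default 2 px). A pixel is a crossing when its LoG
   response changes sign against a 4-neighbour and it is the closer of the
   two to zero. Crossings are filtered by local gradient magnitude: keep
   those above the `magnitude_quantile` (default 0.9) of all crossing
   magnitudes, capped at 0.25x the strongest edge. The cap matters on
   clean images, where essentially all crossings are genuine and a plain
   quantile would discard 90% of a cell's boundary.
2. **Voting.** Each edge pixel casts one vote at every integer distance in
   `[r_min, r_max]` (defaults 1.5-3.5 um, the plausible cell-radius range
   for 4-6 um yeast cells) along its dark-to-bright gradient direction.
   Votes are cast only inward — interiors are bright — which halves
   spurious votes relative to bidirectional casting. The accumulator is
   smoothed with a 4 px Gaussian: an ellipse's normals converge along its
   evolute rather than at a point, and the smoothing integrates that
   segment into one peak.
3. **Seeds.** Local maxima of the accumulator above `min_votes`
   (default 0.05 x 2*pi*r_min_px, an empirical fraction of the ideal
   perimeter vote count that survives smoothing and direction noise),
   followed by greedy non-maximum suppression within `nms_radius_px`
   (default r_max_px — large enough that an elongated cell's split evolute
   peak cannot seed twice, and safe whenever distinct cells are at least
   2 r_max apart).
4. **Reconstruction.** Region growing from each seed over pixels brighter
   than the midpoint of the seed intensity and the image's background mode,
   with edge pixels as barriers; contested pixels go to the geodesically
   nearest seed (multi-source Dijkstra, 8-connected, Euclidean step costs).
   Regions outside `[min_cell_area, max_cell_area]` (defaults 6-60 um^2)
   are discarded; border-touching cells are flagged and excluded from
   counting when `exclude_border` is set.

Region growing was chosen over watershed because each post-condition
(threshold, barrier, geodesic tie-break) is directly testable and there are
no hidden flooding parameters.

## Focus detection

PB foci are diffraction-limited puncta. `detect_foci` smooths the frame
with a small Gaussian (`detection_sigma_px`, default 1 px — a matched
filter for puncta) and takes strict local maxima within
`maxima_radius_px` (default 3 px). Each candidate is measured on the
smoothed frame against its own local background:

* background = median of an annulus `[r_bg_in, r_bg_out)` (defaults 4-7 px);
* peak = maximum over the central disc (`r_int`, default 3 px);
* integrated intensity = background-corrected sum over the disc;
* contrast = (peak - background) / background;
* centroid = intensity-weighted centre of mass of the
  background-subtracted disc.

A focus is retained when it passes **both** filters:

* **contrast >= 0.05** — the 5% contrast threshold, inclusive at the
  boundary (contrast exactly 0.05 is kept);
* **intensity**: either an absolute `intensity_min` in counts, or (the
  default) a local significance test — peak at least `local_significance`
  (default 6) robust standard deviations above the annulus median, where
  the sd is the annulus MAD-based estimate floored by a global MAD
  estimate of the frame. The global floor matters because thousands of
  background candidates are tested per field and some annuli underestimate
  their own noise by chance. A genuine punctum at raw peak SNR 5 sits at
  roughly 11 smoothed-frame sigma (smoothing suppresses pixel noise by
  ~3.5x and the peak by ~1.6x), so the 6-sigma default keeps a twofold
  margin.

Smoothing before measurement preserves integrated intensities up to disc
truncation and leaves between-channel intensity *ratios* untouched, which
is what the stoichiometry procedure consumes.

Foci "intensity" everywhere downstream means the background-corrected
integrated intensity — more robust to PSF width than the peak value.

## Colocalization

Cross-channel matching is greedy over all pairs ordered by centroid
distance, one-to-one, accepting pairs within `d_max` (default 0.25 um,
sub-resolution at the stated optics). On well-separated instances this
equals the optimal assignment (checked against `scipy`'s Hungarian solver
in the tests). The colocalized count is the headline "PB" count; the
single-channel counts are also reported.

## In vivo stoichiometry

Two strains carry the same fluorophore on different PB proteins and are
imaged identically, so abundance ratios equal intensity ratios with no
spectral correction. Per image the `k_brightest` (default 10) foci are
ranked by integrated intensity; the per-image top-k sets are pooled per
condition and their median taken; the reported ratio is median_A/median_B
per timepoint. Per-image ranking is the default because the procedure
presumes at least k foci in every image; `pool_first` switches to ranking
one pooled set per condition. Fewer than k foci is an error unless the
`allow_fewer` fallback is explicitly enabled (and then flagged in output).
Even-k medians are the mean of the central pair.

## Droplet quantification

Droplets are segmented by thresholding one channel (Otsu by default, or
`fixed:<value>`), 8-connected labelling and a minimum-area filter
(default 9 px). Per-channel background is the median of non-foreground
pixels. Mean intensities are measured on a 1 px eroded component
(`measure_erosion_px`) to exclude partial-volume edge pixels whose blurred
values would bias the mean low; set it to 0 for the plain component mean.
Two means are kept per droplet:

* background-subtracted mean — feeds the condensation metric
  `sum(mean x area)` per field, which is then additive across disjoint
  fields and invariant to intensity offsets;
* raw mean — on the same scale as the homogeneous calibration solutions,
  so concentration inversion `c = (I - intercept)/slope` applies directly.

Calibration curves are ordinary least squares on
(concentration, mean intensity) pairs; estimates outside the fitted range
are flagged as extrapolated. The stoichiometric ratio is computed per
droplet and averaged (mean +/- sd), excluding and counting droplets with a
non-positive denominator concentration. Otsu thresholding needs a
non-negligible foreground fraction; fields with one tiny droplet in a
large frame should use a fixed threshold instead.

## Synthetic data

The generator emulates what the analysis assumes and nothing more:

* **Cells**: ellipses with axis ratio <= 1.3, radius 2-3 um, interior
  level sampled per cell at 3.0-3.5x the background (200 counts) —
  interiors are a flat step, with no membrane ring or organelle texture.
* **Foci**: isotropic Gaussians (sigma 1.3 px widefield) added after the
  cell scene is PSF-blurred; amplitudes lognormal (median 300 counts,
  log-sd 0.3). Channel-1 partners of the colocalized fraction sit at the
  channel-0 position plus 0.5 px Gaussian jitter with amplitude divided by
  the planted channel ratio. Decoys are unpaired foci per channel.
* **Droplets**: non-overlapping discs, lognormal radii (median 1.5 um,
  log-sd 0.25); interior intensity `slope*c + intercept` per channel,
  background equal to the intercept.
* **Noise**: Poisson shot noise on expected counts, then additive Gaussian
  read noise (default sd 10), both optional — the sCMOS model at the
  camera counts used. "Peak SNR" in the tests means focus amplitude over
  the total noise sd at the focus.
* **Placement**: cell centres come from a randomly subsampled jittered
  grid that guarantees the minimum spacing (default 7 um = 2 r_max) at any
  requested density; a post-check enforces the no-overlap invariant. Pure
  uniform rejection sampling is above the hard-disc jamming density at the
  50-cell test condition, which is why the grid is used.

Everything is driven by one `numpy` Generator per call, so a seed
reproduces scenes pixel-exactly. Stage-level sub-seeds are derived from
the run seed by hashing stable stage names.

What the generator does **not** model — and what passing tests therefore
do not establish for real data: optical aberrations and anisotropic PSFs,
photobleaching, stage drift, cell crowding/budding, autofluorescence
texture inside cells, out-of-focus light, and droplet coalescence. The
defaults describe a well-behaved acquisition; real datasets will need the
thresholds revisited, which is why every cutoff is a config key.

## Numerical choices and degenerate inputs

* Coordinates are 0-based (row, col); discs and annuli use Euclidean
  distance with the half-open `< radius` convention.
* Intensities stay in raw counts as floats; nothing rescales them.
* Constant images yield zero edges, zero cells, zero foci — not errors.
* Local-maxima plateaus keep only the lexicographically smallest pixel,
  and pixels at the image minimum are never candidates, so flat fields
  yield nothing.
* Ties in seed picking and matching break by ascending (row, col);
  geodesic ties go to the earlier seed.
* Images with zero segmented cells are excluded from PBs-per-cell
  aggregates and listed with a reason, never silently dropped.
* `foci_per_cell` with zero cells is an error, not infinity.

## Problem sizes used in the checks

The self-test and acceptance script run the same recovery properties at
moderate sizes chosen to exercise every stage while staying cheap on one
CPU: cell-count recovery at n in {1, 5, 20, 50} cells; focus
precision/recall over 20 fields of 24 planted puncta; colocalization over
fields of 20 pairs plus 5 decoys per channel; ratio recovery from 10
images per strain of 15 foci each at planted ratios 1-3; droplet
stoichiometry from 50-droplet fields at planted ratios 1-2.7 with 5%
intensity noise; calibration from 6-point series. Each documented
tolerance (10% on recovered ratios, 3% on the calibration slope, 5% on the
concentration round trip) is the sampling error expected at those sizes
with a comfortable margin, not a fit to any particular run.

## Known limitations

* The edge-voting segmenter assumes bright, roughly convex, well-separated
  cells; touching or budding cells are not split.
* Focus detection is 2D and single-frame; no sub-pixel PSF fitting, no
  tracking.
* The published description of the original analysis leaves several
  measurement conventions open (the per-focus intensity definition, the
  droplet "intensity" in the area x intensity metric, per-image versus
  pooled top-k ranking). Each such choice here is explicit, documented
  above, and switchable in the config.
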