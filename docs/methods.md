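# Methods

This note documents the models behind `monotrace`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic benchmarks do
and do not establish about real tracing data.

## Synthetic experiment model

The generator (`monotrace.synthetic`) produces, per animal:

* **Starter cells.** Lateral (dorso-ventral) and anterior-posterior offsets
  from the A1 centre are zero-mean Gaussian with SD = `starter_radius` / 2,
  hard-truncated at `starter_radius` (default 500 µm) — the starter cloud
  falls to zero within ~0.5 mm of the injection centre. Depths are drawn
  layer-first from a per-group laminar profile (mid-layer peak for PV and
  SST, superficial peak for VIP), then uniformly within the chosen layer
  band. Per-animal starter counts are Gaussian-rounded with group means and
  SDs of 238 ± 92 (PV), 254 ± 75 (SST) and 154 ± 30 (VIP).
* **Local input cells.** Lateral and AP positions are Gaussian about the
  starter centroid with a per-group spread `local_spread_sigma` (defaults:
  PV 150 µm, SST 300 µm, VIP 150 µm — SST local inputs are markedly more
  widespread). Depths are uniform across the cortical thickness: local
  inputs arrive from all layers and no sharper laminar claim is needed for
  any test. The count is Poisson with mean
  `inputs_per_starter × (1 − longrange_fraction) × n_starters`.
* **Long-range inputs.** A single multinomial draw over the packaged
  50-region vocabulary. The default probability vector is the per-group mean
  of the packaged proportion table, so the ventral medial geniculate (MGv)
  dominates in every group. The total is an independent Poisson with mean
  `inputs_per_starter × longrange_fraction × n_starters`; local + long-range
  totals are therefore conserved exactly by construction.

Defaults for `inputs_per_starter` are the group mean CIs 31.5 / 36.4 / 39.1
(PV / SST / VIP). `longrange_fraction` defaults to 0.25: local inputs are the
majority of all inputs in every group, and the packaged table's implied total
long-range CI (≈ 6–8) against total CIs of ~30–40 gives a long-range share of
roughly one quarter. Only group-level means are published for these rates, so
per-animal variation beyond Poisson counting noise is not modelled.

Counts are Poisson rather than negative-binomial because no overdispersion
estimate is available; consequences: per-animal CI variation in synthetic
data is narrower than in real animals, and tests of "no group difference"
on synthetic data are easier than in reality.

Seeds are explicit arguments everywhere (plain integers or
`numpy.random.SeedSequence`); there is no global random state, and identical
(config, seed) reproduce byte-identical tables and images.

### Geometry and rendering

Each of the 20 slices (50 µm spacing) carries a 4 mm pia polyline (straight
by default, circular-arc optional), the rhinal-fissure anchor at its ventral
end, layer boundaries at depths 100 / 300 / 450 / 600 / 900 µm (L1, L2/3,
L4, L5, L6; deeper is white matter), and region polygons AuV [0, 1.6 mm),
A1 [1.6, 2.4 mm), AuD [2.4, 4 mm) so that a ~11–15% minority of starters
spills into the neighbouring fields, as observed in tracing data sets.

Rendering paints each cell as a uniform disk (radius 4 px at 2 µm/px,
amplitude 2000) into a 16-bit two-channel frame — starters in both channels,
inputs green-only, red-only cells red-only — over a flat background (100)
with additive Gaussian read noise (SD 50). Deliberately **not** modelled:
point-spread functions, autofluorescence gradients, intensity variation
between cells, 3-D overlap across slices. Detection scores on these renders
are therefore an upper bound for real images; the pipeline's contract on
real data is count-level equivalence with manual annotation, which is what
`compare_auto_manual` (Wilcoxon signed-rank on paired counts) checks.

## Detection and classification

`segment_channel` thresholds a plane absolutely or, in automatic mode, with
**Yen's entropy threshold**. Automatic thresholding must cope with planes
where labelled cells cover well under 1% of the pixels; variance-based
splits (Otsu) then place the threshold inside the background mode (measured
IoU vs truth ≈ 0.26 at noise SD 200), while Yen's criterion stays on the
foreground side (IoU 1.0 at SD 200, 0.91 at SD 400). Automatic mode assumes
the plane contains some signal; for channels known to be empty, pass an
absolute threshold.

`clean_mask` applies morphological opening with a (2r+1)×(2r+1) square
footprint (default r = 1): isolated speckle up to the footprint size is
removed while convex blobs at cell scale keep their exact pixel count.

`classify_cells` labels 8-connected components. A component of the
green∧red overlap mask with area **strictly greater than 5 px** is a starter
("larger than 5 pixels" read literally as a strict inequality, applied to
the overlap component — the plausible alternative, applying it to whole-cell
masks, is not used). Each starter claims the green and red components it
overlaps, so a cell is never double-counted; unclaimed green components
(≥ `min_area_px`, default 5 to mirror the starter rule's scale) are inputs
and unclaimed red components are red_only (potential starters not infected
by the tracer). Raising the overlap threshold can only remove starters
(monotonicity, property-tested).

Evaluation against ground truth uses greedy closest-first matching within
`match_radius` (default 10 µm); each truth cell and each detection matches
at most once.

## Flattened coordinates

`flatten_point` projects a cell onto every pia segment and takes the
Euclidean distance to the nearest foot point as depth y, and the arc length
from the fissure anchor to that foot (linear interpolation within the
segment) as x, **dorsal positive** toward increasing vertex index. Depth is
perpendicular-to-nearest-point rather than columnar — it is a distance to
the pia, not a distance along a radial column; the two coincide for straight
pia. Equidistant feet are resolved toward the smaller arc length (logged).
The implementation is vectorised over segments and is verified against an
independent per-segment brute-force oracle to 1e-6 relative tolerance.

Layer bins are half-open [lower, upper): a cell exactly at a boundary depth
belongs to the deeper bin, and depth ≥ the last boundary is white matter,
which is excluded from layer-fraction profiles. Region assignment is 2-D
point-in-polygon per slice; a point on a shared edge goes to the first-listed
polygon (logged), uncovered points report "other". Slices stack along the AP
axis at `slice_index × slice_thickness`. `center_population` aligns animals
by subtracting the per-animal starter mean x from all cells, leaving depth
and layer untouched.

## Statistics

* **CI** = inputs / starters; animals without starters are excluded with an
  error (division is undefined, and such an animal carries no tracing
  signal).
* **Proportions** are computed over long-range columns only (A1/AuD/AuV
  excluded); all-zero animals are dropped and logged. The 0.2%
  display-threshold view exists for plotting only and never feeds statistics.
* **Distances** are per-axis (DV uses flattened x, AP the slice coordinate),
  since the two axes are analysed separately; a 2-D in-plane mode
  (x, depth) is also provided. `pairwise` uses all input × starter pairs
  within an animal (never across animals); `centerline` measures each input
  against the starter-population mean coordinate. Both are provided because
  the two definitions answer slightly different questions (dispersion of the
  joint cloud vs distance from the injection centre) and published analyses
  mix them; no attempt is made to prefer one.
* **Group comparisons**: Kruskal–Wallis omnibus (midranks for ties, logged);
  pairwise Tukey HSD runs only when the omnibus rejects at α = 0.05 — a
  mixed nonparametric-omnibus / parametric-post-hoc convention reproduced as
  used in this literature, with Dunn's rank z-test available via
  `posthoc="dunn"` as the statistically conventional alternative. All tests
  are two-sided. No multiple-testing correction is applied across regions;
  region-by-region scans are exploratory by design and callers should treat
  isolated p < .05 hits accordingly.
* Degenerate inputs are flagged rather than silently passed: identical
  constant groups and all-zero paired differences report p = 1 with a
  degeneracy flag; constant vectors are an error for Pearson correlation.

## Packaged long-range table

The packaged CSV stores, per animal and region, the printed CI and
proportion values (4 PV, 6 SST, 4 VIP animals; 49 named regions + "Others").
`load_table` verifies a frozen SHA-256 checksum so silent corruption fails
loudly. Known quirks preserved verbatim: the region ECIC appears twice
(kept as `ECIC` and `ECIC_2`); one contralateral insular row is named
`InsC_contra` in the CI block but `GI_contra` in the proportion block (the
CI-block name is canonical, the alternate is noted in the glossary);
"Others" is an opaque aggregate and is never expanded. Whether the printed
CIs use all starters or only A1-confined starters is not recorded; values
are stored as printed with no correction. Per-animal proportion sums land in
[0.998, 1.005] (3-decimal rounding), and the implied-total-CI dispersion is
< 5% for every animal with the default proportion floor of 0.02 (below
which rounding error dominates the ratio).

## Problem sizes and numerical choices

The test suite runs scaled-down conditions chosen to keep each stochastic
check well-powered: 2 animals/group with ~40 starters and 6 inputs/starter
for end-to-end tests; 10⁴ draws for distribution-recovery checks (binomial
3-SD bands, 5% SD recovery); 4 animals/group × 200 inputs × 100 starters for
the wide-vs-narrow KS comparison (80 000 pooled pairwise distances per
group); 500 replicates for the Kruskal–Wallis type-I-error calibration; one
2000 × 500 px slice with 100 cells for detection scoring. The acceptance
script uses the full default group rates (e.g. PV 31.5 inputs/starter,
~238 starters/animal, 4 animals).

Tolerances: probability vectors must sum to 1 within 1e-9; proportion rows
within 1e-12; flattening agrees with the brute-force oracle to 1e-6
relative; statistical checks use 3-SD / 3-SE bands.

## Known limitations

* The deterministic threshold classifier is a different mechanism from
  trainable pixel classification; it meets the same count-level contract on
  renders, but real images with uneven illumination will need the absolute
  threshold per slice or upstream flat-field correction.
* Region polygons are user-supplied simplifications; no atlas registration,
  nonlinear deformation, or automatic pia detection is attempted.
* Contralateral cells are distinguished by slice metadata / polygon tags,
  not by geometry; the synthetic generator does not place contralateral
  cells in space (they enter as region counts only).
* Merged blobs in very dense fields are counted once per connected
  component; at the default render density this costs ≲ 2% recall, but CI
  estimates from images of extremely dense local fields will be biased low.
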