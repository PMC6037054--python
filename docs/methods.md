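# Methods

## Segmentation model

The detector assumes fluorescence z-stacks in which lipid droplets are the
brightest structures: compact puncta well above the cytoplasm level, which
itself sits above the extracellular background. Detection is per plane:

1. **Quantization.** Intensities are partitioned into `n_levels` (default 5)
   ordered classes. The default quantizer is multilevel Otsu — thresholds
   minimizing the total count-weighted within-class variance — computed
   exactly by dynamic programming over a 256-bin histogram
   (O(levels·bins²); a `scikit-image`-style exhaustive search is
   intractable at five classes and is used only as a cross-check in tests).
   Thresholds are applied to the raw intensities, so the pixel→level mapping
   is exactly monotone. An equal-width quantizer is available as a fallback.
   With fewer distinct intensities than levels, the distinct values are
   rank-spread over the level range so the brightest pixels always occupy
   the top class; a constant plane yields all-zero levels and a degeneracy
   warning rather than an exception.
2. **Detection layer.** Only the top class is considered droplet candidate
   material. Lower classes separate cells from background and are not
   revisited.
3. **Shape-driven recursion.** An 8-connected candidate component is
   accepted if its area is at most `max_area` (800 px) **and** its
   circularity 4πA/P² is at least `circularity_min` (0.6). Both
   inequalities are strict in the violating direction: exactly 800 px does
   not recurse, and after merging, exactly `min_area` (4 px) survives.
   A violating component is re-quantized — `n_levels`-class thresholds
   computed from its own pixel intensities — and only its top class, a
   strict subset, continues one recursion level deeper (up to `max_depth`,
   default 10). This per-component re-thresholding adapts to each blob's
   brightness, so a dim touching pair and a bright one both split. A
   component that cannot shrink (uniform intensity or empty/full top class)
   or that is still violating at the depth cap is accepted as-is and
   flagged `forced`; discarding such objects would silently delete the
   brightest saturated droplets, whereas the flag keeps them auditable.
4. **Merge and filter.** Per-plane accepted masks are OR-ed across the
   stack (droplets appear in several neighbouring slices; no 3D linking is
   attempted). Merged objects with ≥ 1 px on the exclusion mask are removed
   with reason `mask_overlap` (the conservative any-overlap reading of
   "belongs to an excluded cell"; checked before the size rule), and
   objects below `min_area` with reason `below_min_area`. Survivors are
   relabeled 1..K.
5. **Features.** All features are measured against the maximum-intensity
   projection of the stack. The projection is the natural reference once
   per-plane masks have been merged to 2D; the per-droplet signal measure
   is the area-integrated projection intensity.

### Numerical choices

- **Perimeter/circularity.** Perimeter is the 4-direction Crofton estimator
  on the 1-px-padded component mask. Among the standard discrete contour
  estimators it is the only one whose disk circularity increases
  monotonically toward 1 with radius (0.83, 0.88, 0.94, 0.97 for radii 3,
  5, 10, 20), which makes the `circularity_min` cutoff interpretable.
  Discretization can push small compact rasters slightly above 1; values
  are clipped to 1, and a single pixel is 1 by convention. The 0.6 default
  cutoff accepts digital disks and squares and rejects elongated ridges
  (a 1×40 line scores ≈ 0.09).
- **Structure guard.** A plane whose top threshold lies within
  `noise_margin` (default 10) robust standard deviations (1.4826·MAD) of
  the plane median is treated as degenerate and contributes no candidates.
  On pure detector noise the top Otsu class is merely the upper noise tail
  (margin ≈ 1–2); on any plane with genuine bright structure the margin is
  of order 100. Without the guard, the OR-merge of ten noise tails would
  produce spurious ≥ 4 px objects on droplet-free images. Margin 0 disables
  the guard.
- **Determinism.** The pipeline is pure: identical inputs and parameters
  produce bit-identical label images and tables.

### Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `n_levels` | 5 | classes | quantization depth per thresholding step |
| `max_area` | 800 | px | recursion trigger (strictly larger recurses) |
| `min_area` | 4 | px | post-merge removal (strictly smaller removed) |
| `circularity_min` | 0.6 | — | recursion trigger for non-compact shapes |
| `max_depth` | 10 | levels | recursion cap (then forced acceptance) |
| `connectivity` | 8 | — | component connectivity (4 configurable) |
| `quantizer` | otsu | — | `otsu` or `equal-width` |
| `noise_margin` | 10 | robust σ | degenerate-plane guard |

Areas are expressed in pixels of the acquisition geometry; at other
magnifications `min_area`/`max_area` should be rescaled rather than treated
as constants.

## Quantification

Droplets are assigned to cells by the cell label under the droplet's
centroid pixel; droplets on background are reported separately and counted
nowhere. Zero-droplet cells are kept in every summary — both the per-cell
mean total intensity and the 'cut' × droplet-presence contingency depend on
them. The contingency is oriented rows = (cut, non-cut), columns =
(no droplets, has droplets), so `alternative="greater"` in the Fisher test
asks whether 'cut' cells are enriched among droplet-free cells. A pre-built
phenotype table can be supplied instead of a label image when cell
assignment was done elsewhere.

## Statistics

- **Doubling time.** DT = 1/k with k the least-squares slope of log₂(OD)
  versus time; base 2 is the only base for which 1/slope is directly a
  doubling time. The exponential phase is chosen automatically as the
  contiguous window of at least a quarter of the series maximizing the
  log-linear r² (ties broken toward longer, then earlier, windows; windows
  with zero OD variance are skipped). Within a true exponential stretch r²
  grows with window span, so the maximizer extends to the lag and plateau
  bends and then stops. The window search uses prefix sums (O(1) per
  window). Non-positive slopes raise a no-growth error. The estimator is
  invariant under OD rescaling.
- **t-tests.** Unpaired tests use the Welch unequal-variance form (the
  safer default when variances are unknown; recorded in
  `TestResult.method`). Paired data with all-zero differences return
  t = 0, p = 0.5 by null symmetry; two constant samples are a degenerate
  input and raise.
- **Wilcoxon rank-sum.** Exact null distribution when the pooled sample has
  ≤ 20 observations and no ties (cutoff configurable), tie-corrected
  normal approximation with continuity correction otherwise. Tests verify
  both routes against an independent dynamic-programming enumeration of the
  rank-sum distribution.
- **Fisher exact.** Hypergeometric tail under fixed marginals; a zero
  marginal means every table under the null is identical, so p = 1 by
  convention. Tests verify against full enumeration on all 2×2 tables with
  grand total ≤ 30.
- No multiple-testing correction is applied; p-values are per-comparison.

## Synthetic data

`simulate_stack` renders what the detector assumes: 512×512 16-bit stacks
of 10 slices 0.3 µm apart; non-overlapping axis-aligned rods (length 40–70
px, width 12–18 px, ≈ 0.1 µm/px) at cytoplasm level 1200 on background 200;
droplets as Gaussian spots (radius 3–5 px, truncated at twice the radius)
with peak amplitudes 12 000–17 000 counts; Poisson photon noise plus
Gaussian read noise (σ = 60). Droplet peak brightness and radius co-vary
through a shared latent size variable with lognormal scatter (σ = 0.05) —
larger droplets carry more dye — which is also what makes area-integrated
intensity a faithful rank proxy for planted brightness. Axial spread is a
wide Gaussian (σ_z = 5 slices) with droplet centres in the middle of the
stack, as in widefield imaging where out-of-focus droplet light reaches
every slice; the amplitude floor is set so that the top quantization class
captures the cores of the dimmest droplets in their focal planes. A
configurable fraction of droplets is planted as touching pairs (exercising
the recursive splitting path), droplet counts per cell are zero-inflated
Poisson (modelling droplet-free subpopulations), and dead cells are
rendered at 40 % cytoplasm brightness with their footprints fully covered
by the exclusion mask, so mask-overlap filtering can be verified against
ground truth exactly.

What the simulator does **not** model: optical point-spread functions
beyond Gaussian spots, photobleaching, uneven illumination, cell crowding
or overlap, out-of-focus debris, and autofluorescence texture. Passing
recovery tests therefore demonstrate the algorithm's correctness on its own
assumptions, not segmentation accuracy on real micrographs. In particular,
on an image containing cells but no droplets at all, the brightest
structure is the cytoplasm itself and the detector will report compact
cytoplasm fragments — the method has no notion of "droplet-ness" beyond
relative brightness, and its intended inputs are images acquired from
stained cells.

`simulate_growth` produces lag / exponential / plateau trajectories
(defaults: 0.05 starting OD, 2 h lag, 3 h doubling time, plateau at 0.6,
10-min sampling over 12 h, 2 % multiplicative lognormal noise) matching a
plate-reader run. `simulate_phenotypes` draws per-cell droplet counts from
a zero-inflated Poisson (mean 3, zero fraction 0.3) and 'cut' status
Bernoulli-conditional on droplet presence (defaults 0.6 versus 0.05),
planting the droplet-deficiency association at a strength recoverable by
the Fisher test at n = 300 cells.

All generators are pure functions of (parameters, seed); a single integer
seed drives one `numpy` generator per call.

## Problem sizes

Unit tests run on 256×256 stacks and reduced replicate counts; the
dedicated end-to-end suite uses the full study conditions (100 seeds of
512×512×10 stacks with 12 droplets, 10 000 t-test replicates, 200 growth
curves). `scripts/acceptance.py` re-runs the same computations with 40
recovery seeds and 5 exclusion seeds; these sizes are the package's
reporting defaults and keep a full desk-scale rerun under a minute.

## Known limitations

- Only the top quantization class seeds detection; dots dimmer than the
  fifth intensity class of their plane are invisible to the detector.
- The merge step is 2D: droplets overlapping in (x, y) at different depths
  fuse into one object.
- Centroid-containment cell assignment can mis-assign droplets whose
  centroid falls just outside a concave cell footprint.
- The auto-window doubling-time fit assumes a single exponential phase;
  diauxic curves will yield the best-fitting single stretch.
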