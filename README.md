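# dropletquant

Detection and quantification of lipid droplets in fission-yeast
(*Schizosaccharomyces pombe*) fluorescence microscopy, for labs measuring
neutral-lipid content from BODIPY- or GFP-marker-stained cells. The package
implements a recursive multilevel-threshold spot detector for 16-bit
z-stacks, per-cell aggregation of droplet signal, the small-sample
statistics used to compare conditions, and growth-curve doubling-time
estimation — together with simulators that generate all of these inputs with
known ground truth, so the whole pipeline is testable without microscope
data.

## The method

**Segmentation.** Each focal plane of a z-stack is quantized into five
intensity classes (multilevel Otsu: thresholds minimizing the
count-weighted within-class intensity variance). The top class is the
detection layer. Its 8-connected components are accepted as droplet dots if
they are small (area ≤ 800 px) and compact (circularity
4πA/P² ≥ 0.6, Crofton perimeter); a component violating either rule is
re-thresholded — its own pixel intensities are quantized again into five
classes and only their top class survives — and the shrunken candidates are
examined recursively at a higher threshold. A component that cannot shrink
(uniform intensity, or recursion cap reached) is accepted as-is and flagged
`forced`. Per-plane dot masks are merged across the stack by pixelwise OR;
objects overlapping a user-supplied exclusion mask (dead or partially imaged
cells) or smaller than 4 px are removed; features (area, centroid,
perimeter, circularity, area-integrated and maximum intensity) are extracted
for every object against the maximum-intensity projection.

**Quantification.** Droplets are assigned to cells by centroid containment
in a cell label image; per-cell records (droplet count, total integrated
intensity, 'cut' mitotic-failure status) feed a 2×2 contingency of 'cut'
status × droplet presence.

**Statistics.** One-sided paired and Welch t-tests; one-sided Wilcoxon
rank-sum (exact null distribution for pooled n ≤ 20 without ties, the
tie-corrected normal approximation otherwise); one-sided Fisher exact test
(hypergeometric tail); and culture doubling time DT = 1/k, where k is the
least-squares slope of log₂(OD) versus time over the exponential phase
(chosen automatically as the contiguous window, at least a quarter of the
series, maximizing the fit's r²).

## Worked example

```python
import dropletquant as dq

params = dq.ImageSimParams(n_cells=12, droplets_per_cell=("fixed", 1), seed=42)
stack, exclusion, truth, cell_labels = dq.simulate_stack(params)
result = dq.segment_stack(stack, exclusion)
print(f"planted {truth.n_droplets} droplets, detected {result.n_droplets}")
# planted 12 droplets, detected 12

print(result.droplets[["droplet_id", "area_px", "circularity",
                       "integrated_intensity"]].head(3))
#    droplet_id  area_px  circularity  integrated_intensity
# 0           1       21          1.0              275943.0
# 1           2       21          1.0              259206.0
# 2           3       37          1.0              467293.0

assignment = dq.assign_droplets_to_cells(result.droplets, cell_labels)
print(dq.per_cell_mean_total(assignment.table))   # 274754.8

fit = dq.doubling_time(dq.simulate_growth(dt=3.0, noise_sigma=0.02, seed=42))
print(f"doubling time {fit.dt:.2f} h")            # doubling time 3.01 h

pheno = dq.simulate_phenotypes(seed=42)
table = dq.cut_by_droplet_contingency(pheno)      # [[57, 8], [34, 201]]
print(dq.fisher_exact_one_sided(table, "greater").p_value)  # 1.31e-28
```

The segmentation found every planted droplet; the per-droplet
`integrated_intensity` is the sum of maximum-projection intensities over the
object's pixels (the per-droplet signal measure). The contingency table
rows are (cut, non-cut) and columns (no droplets, has droplets): 57 of 65
'cut' cells lack detectable droplets, and the one-sided Fisher test
confirms the planted enrichment.

The same steps are available from the shell:

```sh
dropletquant simulate stack --seed 42 --out sim/
dropletquant segment --stack sim/stack.tif --mask sim/exclusion.tif --out seg/
dropletquant quantify --droplets seg/droplets.csv --cells sim/cells.tif --out cells.csv
dropletquant growth --curve growth.csv --window auto
dropletquant test --method fisher --alt greater --in table.csv
```

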