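# nasallom

Comparative allometry of the amniote nasal cavity: does nasal-cavity size
scale differently with *head* size — but not with *body* mass — between
endotherms (birds, mammals) and ectotherms (crocodylians, turtles,
lepidosaurs)? And where does a fossil theropod's reconstructed airway fall
relative to the two groups' allometric lines?

The package is aimed at comparative morphologists and palaeophysiologists
who have (or simulate) per-specimen measurements of nasal cavity, skull
and convex-hull head-model size plus a time-calibrated phylogeny, and who
want the full inferential chain — voxel morphometry, phylogenetic
regression, conditional group tests, fossil placement — as tested,
scriptable code.

## The model

All sizes are analysed on log10 axes, so a power law `Y = a·X^b` becomes
the line `log Y = log a + b · log X`. For each size proxy *X* (body mass,
skull volume, convex-hull head-model volume) and response *Y* (surface
area or volume of the whole nasal cavity or of its respiratory region
only), group-specific lines are fitted three ways:

- **OLS** — ordinary least squares;
- **SMA/RMA** — standardized major axis, slope `sign(r)·s_y/s_x`;
- **PGLS** — generalized least squares with residual covariance
  `σ² C`, where `C[i,j]` is the shared root-to-MRCA branch length of tips
  *i* and *j* under Brownian motion on the phylogeny.

Group comparison is conditional: first the slopes are tested (Wald test
on the group×X interaction for OLS/PGLS; Warton-style likelihood-ratio
common-slope test for SMA). Only if the slopes are indistinguishable is
the intercept tested at a common slope (ANCOVA / phylogenetic ANCOVA /
SMA elevation test); otherwise the intercept is reported as *not tested*.

A fossil with log10 size `x` and log10 bony airway volume `y` is placed
by the dimensionless index

```
ρ = (y − ŷ_ecto(x)) / (ŷ_endo(x) − ŷ_ecto(x))
```

(0 on the ectotherm line, 1 on the endotherm line), reported both for the
bony-bounded volume and after the 40–60% soft-tissue correction. The bony
airway itself is extracted from a labelled head volume by four
osteological constraint planes (nostril, antrum boundary, choana,
mesethmoid cap).

## Worked example

```python
import numpy as np
from nasallom import (AnalysisConfig, SimulationConfig, run_full_analysis,
                      simulate_dataset, simulate_tree)

cfg = SimulationConfig(n_tips=50, seed=7)
tree = simulate_tree(cfg)                       # 100-Ma ultrametric Yule tree
data = simulate_dataset(tree, cfg, head_offset_endo=0.3)

report = run_full_analysis(
    AnalysisConfig(methods=["pgls"]), data, tree=tree,
    fossil={"skull_vol_mm3": 2.0e4, "hull_vol_mm3": 3.2e4,
            "airway_vol_mm3": 1100.0},
)
print(report.summary_table().to_string(index=False))
```

```
        comparison     response  pgls_slope_p  pgls_intercept_p
nasal_vs_body_mass surface_area      0.980362          0.513031
nasal_vs_body_mass       volume      0.980362          0.513031
nasal_vs_skull_vol surface_area      0.758546          0.000555
nasal_vs_skull_vol       volume      0.758546          0.000555
 nasal_vs_hull_vol surface_area      0.758546          0.000555
 nasal_vs_hull_vol       volume      0.758546          0.000555
 resp_vs_skull_vol surface_area      0.758546          0.000555
 resp_vs_skull_vol       volume      0.758546          0.000555
  resp_vs_hull_vol surface_area      0.758546          0.000555
  resp_vs_hull_vol       volume      0.758546          0.000555
```

The generated data carry an endotherm intercept offset linked to head
size only — and that is exactly what the report shows: body-mass
comparisons are null (slope p = 0.98, intercept p = 0.51), while every
head-size comparison finds a strong intercept difference (p ≈ 0.0006) at
a common slope. Surface-area rows duplicate the volume rows because the
generator derives areas from volumes by exact 2/3-power scaling.

The attached fossil (bony airway 1100 mm³ at skull volume 2×10⁴ mm³)
lands almost exactly midway between the fitted lines:

```python
pl = report.fossil_placements["resp_vs_skull_vol"]
print(pl.relative_index_bony)        # 0.499
print(pl.relative_index_corrected)   # (-1.08, -0.38)
```

ρ ≈ 0.5 for the bony-bounded volume; after the 40–60% soft-tissue
correction the plausible airway falls below the ectotherm line
(ρ < 0).

The same chain is available from the shell:

```bash
nasallom simulate --n-tips 50 --seed 7 --out-dir work/
nasallom compare work/measurements.csv --tree work/tree.nwk --out-dir work/report/
nasallom measure phantom.nii.gz --labels labels.json -o row.csv
nasallom reconstruct phantom.nii.gz --landmarks lm.json -o cropped.nii.gz
nasallom place-fossil --x 4.3 --y 3.04 --fits fits.json --correction 0.4:0.6
```

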