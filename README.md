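# sctipping

Trajectory-bifurcation and tipping-point analysis for time-course
single-cell proteomic/metabolic snapshots.

When a plastic cancer cell population adapts to a targeted drug, different
subpopulations can travel *different* routes through cell-state space to the
same drug-tolerant destination. Snapshot single-cell assays (for example
antibody-barcode chips measuring ~20 proteins and metabolites per cell at a
handful of treatment days) cannot track individual cells, but the statistical
structure of the snapshots still reveals the routes: a low-dimensional
decomposition separates the time-dependent drug response from a
lineage-dependent bifurcation, and critical-transition statistics locate the
subpopulation closest to the "tipping point" of each route — the most
promising stage to attack with a second drug.

`sctipping` packages that analysis for cell × analyte tables of positive
fluorescence-derived levels with a per-cell day label, and ships a synthetic
data generator that plants the same structure with known ground truth so
every stage can be validated end to end.

## The model

Log levels are decomposed by **surprisal analysis**: for analyte *i* in cell
*c*,

```
ln X_i(c) = λ0(c) G_0i + Σ_j λ_j(c) G_ij ,
```

a steady-state term plus a few deviation **modules**, each the product of a
cell-dependent **influence score** λ_j(c) and a cell-independent analyte
pattern G_ij. Numerically this is the singular value decomposition of the
uncentered log matrix; scores carry the singular value (λ_j = u_j s_j) and
loadings are unit vectors. In drug-adaptation data module 1 tracks treatment
time and module 2 splits the population into two lineage paths (its sign
convention is pinned so the MITF-high, melanocytic path has negative
scores).

Cells are then linked in a sequential k-nearest-neighbour graph (within and
between adjacent days), clustered per day (Ward linkage, elbow-selected k),
and each cluster is scored with two critical-transition indices computed on
a marker subset:

* **SNAI** = 1 / det(R), the reciprocal determinant of the analyte–analyte
  Pearson correlation matrix (≥ 1; diverges as correlations concentrate);
* **Ic** = ⟨|r_analyte-pairs|⟩ / ⟨|r_cell-pairs|⟩, mean absolute
  analyte-pair correlation over mean absolute cell-pair correlation.

Both rise near a critical transition, where analyte–analyte correlation
grows and cell–cell correlation falls. The per-path argmax cluster is the
tipping-point candidate. Its analyte–analyte **Spearman correlation
network** (edges kept when the pair's p-value survives a per-network
Bonferroni correction) is summarized by node degree and eigenvector hub
scores, nominating the hub analytes that maintain the near-critical state.

## Worked example

Simulate a 4-day series (50 cells/day) and run the whole pipeline:

```python
import sctipping as st
from sctipping.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulate=st.GeneratorConfig(n_cells_per_day=(50, 50, 50, 50)),
    out_dir="run", seed=11,
)
result = run_pipeline(cfg)
print(result.decomposition.summary())
```

```
Surprisal decomposition
=======================
cells: 200   analytes: 20   modules: 2   centered: False

component  singular value  variance fraction
        0        415.0626            0.99842
        1         11.6979            0.00079
        2          9.6658            0.00054
        3          3.0320            0.00005
        4          1.8956            0.00002
module 1 top loadings: Ki67 (-0.48), AXL (+0.35), NGFR (+0.33)
module 2 top loadings: MITF (+0.57), MART1 (+0.47), Slug (+0.38)
```

The steady state dominates (component 0); module 1 is the drug-response
axis (proliferation marker Ki67 falls, resistance markers AXL/NGFR rise
with treatment) and module 2 is the lineage axis (MITF/MART1/Slug). The
run directory's `summary.json` reports, per path, the tipping cluster and
its top hub analytes:

```
"paths": {
  "upper": {"tipping_cluster": 4, "day": 3, "n_cells": 18,
            "snai": 63275.8, "ic": 0.442,
            "top_hub_analytes": ["MART1", "p-LKB", "MITF"]},
  "lower": {"tipping_cluster": 5, "day": 3, "n_cells": 32,
            "snai": 656.6, "ic": 0.243,
            "top_hub_analytes": ["N-cadherin", "TNFR", "HIF1a"]}
}
```

Both detected tipping clusters sit at the intermediate day (day 3), where
the generator plants them, and the hub analytes recover each path's planted
factor: the melanocytic/metabolic program on the upper (MITF-high) path and
the TNFR/N-cadherin/stress program on the lower path — each path suggesting
its own co-drugging target.

The same stages are available from a shell:

```
sctipping simulate --seed 11 --n-per-day 50 --table table.csv --truth truth.csv
sctipping decompose --input table.csv --out-dir out/
sctipping run --config config.yaml
```

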