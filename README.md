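# iopn-tme

Spatial deconvolution of the immune microenvironment of pancreatic
**intraductal oncocytic papillary neoplasms (IOPN)** — a tested, reusable
implementation of the digital-pathology analysis chain for phenotyped
cell-coordinate maps, plus the conventional immunohistochemistry (IHC)
scoring used alongside it.

IOPNs are rare pancreatic intraductal tumors with a strikingly rich
immune infiltrate.  Given a per-cell table (μm coordinates, tumor /
immune / stroma class, marker phenotype), the package:

- groups cells into **200 μm raster-scanned cylindrical neighborhoods**
  laid on a grid over the ROI, each summarized by its composition vector
  `c = (n_tumor, n_CD4, n_CD8, n_CD20, …) / n_total`;
- clusters neighborhood compositions with a **self-organizing map
  (SOM)** and groups the SOM nodes into *k* regions by Ward linkage,
  choosing *k* with the **Davies-Bouldin criterion**
  `DB = (1/k) Σᵢ maxⱼ≠ᵢ (Sᵢ+Sⱼ)/Mᵢⱼ` (minimum wins); for these tumors
  this recovers two regions — an immune-rich tumor-core region (Re1) and
  a tumor-dense periphery (Re2);
- computes **region extensions** (% of a tissue component's
  neighborhoods per region) and per-region **median compositions**, and
  compares intraductal vs invasive components phenotype-by-phenotype
  with Student's t-tests;
- aligns serial IHC sections to the H&E reference (similarity / affine
  least squares + ICP) and projects marker-positive cells into one
  composite map;
- implements the **semi-quantitative 0–5 per-HPF score** (PD-1: single
  most positive field; other markers: mean of the five most positive
  fields), **PD-L1 TPS/CPS**, and **MMR retained/loss** calls;
- reproduces the 15-case cohort summary statistics from the packaged
  per-case table.

Because no cell-level data are deposited for this tumor type, a
first-class **synthetic-tissue generator** plants the assumed structure
(two-zone geometry, published region composition vectors, serial-section
transform + jitter + dropout) with full ground truth, so every stage is
testable end to end.

## Worked example

```python
from iopn_tme.pipeline import (
    simulate_two_zone_case, analyze_regions, tissue_roi, core_periphery_medians,
)

cells, truth, spec = simulate_two_zone_case(seed=1)   # ~21,000 cells
analysis = analyze_regions(cells, roi=tissue_roi(spec), seed=1)
print({k: round(v, 4) for k, v in analysis.model.db_scores.items()})
print({k: round(v, 2) for k, v in core_periphery_medians(analysis).items()})
```

prints

```
{2: 0.4313, 3: 0.6358, 4: 0.6787, 5: 0.7048, 6: 0.7856}
{'k': 2, 'core_median_cd8_pct': 36.67, 'periphery_median_tumor_pct': 89.66}
```

The Davies-Bouldin index is minimized at k = 2, so two regions are kept.
The recovered immune-rich core region has a median per-neighborhood CD8
fraction of 36.7% (planted: 37.18%) and the tumor-dense periphery a
median tumor fraction of 89.7% (planted: 89.43%) — the pipeline recovers
the planted spatial architecture from raw cell coordinates alone.

The numbered drivers under `analysis/` run the full study in order
(`01_simulate_tissue.py` … `05_cohort_statistics.py`), writing tables to
`results/`.  For example `python analysis/05_cohort_statistics.py` prints
the cohort means (CD3 4.6, CD4 3.1, CD8 4.1, CD20 1.9, PD-1 3.3,
TPS 10.1%, CPS 12.3 …) and the paired t-tests
(CD3 vs CD20: p = 5.4e-07; CD8 vs CD4: p = 9.2e-04).

There is also a CLI:

```sh
iopn-tme simulate --seed 1 --outdir results
iopn-tme regions  --seed 1 --outdir results
iopn-tme report   --seed 1 --outdir results
```

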