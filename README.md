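# immunogradient

CD8+ cell density-gradient analysis across the tumor epithelium–stroma
interface, with the survival-modeling pipeline that turns the gradient into
a recurrence-risk stratifier.

## The problem

In non-muscle invasive papillary urothelial carcinoma (NMIPUC) treated with
BCG immunotherapy, recurrence risk relates not to how many cytotoxic CD8+
T cells a tumor contains, but to *where* they sit relative to the
epithelium–stroma interface. Papillary tumors have no broad invasive
margin — tumor–host interaction happens along thin, elongated fronds — so
the interface has to be sampled band by band at 10 µm resolution on both
sides. This package implements that analysis for anyone with (a) a labeled
tissue mask per slide (epithelium / stroma / artifact, from any tissue
classifier), (b) a CD8+ cell-centroid table, and (c) a clinical table with
recurrence-free survival (RFS); synthetic generators for all three make
the entire pipeline testable without patient data.

## The quantities

Each epithelium/stroma pixel within 150 µm of the interface gets a signed
band rank *r*: magnitude `ceil(d / 10 µm)` from its Euclidean distance *d*
to the nearest retained boundary (boundaries shorter than 1000 µm are
removed as classifier noise), positive on the epithelial side, negative on
the stromal side. With ρ\_r the CD8+ density (cells/mm²) in band *r*:

* **Immunodrop** — `ID(r) = ρ₋ᵣ / ρᵣ` — the stromal-to-epithelial density
  ratio of the rank-r band pair. ID > 1 means CD8+ density drops on
  entering the epithelium.
* **Center of mass** — `CM = Σᵢ rᵢ·ρᵢ / Σᵢ ρᵢ` over the signed ranks of the
  interface zone. CM < 0 means the CD8+ mass is skewed toward the stroma.

Both are evaluated over a grid of zone widths (20–300 µm). Downstream, the
indicators join grade, stage and tumor-history covariates in a Cox
proportional-hazards procedure: administrative censoring at 60 months, an
event-stratified train/test split, univariable screening at p < 0.05,
exhaustive enumeration of covariate combinations keeping models whose
covariates are all significant, 5-fold cross-validated ranking by mean
validation Harrell's C-index, and finally a 3-point risk score (1 point
each for G3 grade, positive reTUR or recurrent tumor, and medium-or-high
ID tertile; 0–1 → low, 2 → intermediate, 3 → high).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. `01_simulate_slides.py` generates eight papillary slides whose
programmed epithelial decay varies from ~0 (flat) to ~0.8 per band;
`02_spatial_gradients.py` measures their gradients:

```
    slide  decay_epithelial  interface_um  n_cd8_cells  id_10_20um  cm_0_20um
slide_001          0.203164        3504.0          228    1.037114   0.038106
slide_005          0.791276        3708.1          201    4.652160  -0.534370
...
Spearman(decay, ID 10-20um) = 0.52
```

The nearly-flat slide (decay 0.20) measures ID ≈ 1.04 and CM ≈ 0.04 —
no gradient — while the steepest slide measures ID ≈ 4.7 and CM ≈ −0.53:
a strong density drop into the epithelium, the configuration associated
with shorter RFS. `03_survival_models.py` wires these measured IDs into a
simulated 157-patient cohort (hazard on tumor history, G3 and ID) and runs
the full selection procedure:

```
best model: id_value + retur_or_recurrent
  id_value               HR = 6.6277, p = 0.0000
  retur_or_recurrent     HR = 3.7471, p = 0.0001
  train C = 0.7776, mean validation C = 0.7752, test C = 0.8352
```

`04_risk_score.py` stratifies the same cohort by the combined score; all
three pairwise log-rank comparisons separate (low vs intermediate
p = 0.0074, low vs high p < 0.0001, intermediate vs high p = 0.0003).

There is also a CLI for running the stages on your own files from a single
YAML config: `immunogradient generate|spatial|survival|all --config run.yaml`.

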