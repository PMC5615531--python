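# geovuln

Socio-environmental vulnerability mapping of geriatric depression risk.

`geovuln` is a reusable Python implementation of a data-driven framework for
estimating and mapping late-life depression risk in a high-density city from
individual survey data and built-environment GIS layers. It is aimed at
spatial epidemiologists and urban-health researchers who want to go from a
geocoded cohort plus land-use/vegetation/building rasters to (1) adjusted
odds ratios for social and built-environment risk factors, (2) an
odds-ratio-weighted vulnerability index, (3) a city-wide risk map aggregated
to planning units, and (4) a validation of that map against the cohort
itself. Because the original cohort and GIS layers of this design are not
publicly deposited, the package ships a first-class synthetic-city module
that reproduces the study conditions, so the entire pipeline is testable
end to end.

## The model

Depression cases are defined by the 15-item Geriatric Depression Scale:
GDS-15 ≥ 8 is a case. For each subject, four built-environment measures are
computed in a 400-m circular buffer around the residential address from
rasters resampled to a fine working grid: % residential area, % vegetation,
and the mean and standard deviation of building height over built cells
(the height measures are then rank-normalised to 0–100 percentiles across
the sample). Risk is modelled with a binomial logistic regression fitted by
iteratively reweighted least squares (IRLS):

```
logit P(case) = β0 + β1·older_age(≥80) + β2·male + β3·not_married
              + β4·low_education + β5·living_alone
              + β6·pct_residential + β7·pct_vegetation
              + β8·avg_height_pctile + β9·std_height_pctile
              + β10..β15 · (dementia, physical activity, cardiovascular,
                            respiratory, alcohol, smoking)
```

Model 1 uses the social factors only, Model 2 the environmental measures
only, Model 3 both; the lifestyle/medical confounders are always included,
and rows with missing values are excluded (complete-case analysis).
Adjusted odds ratios are `exp(β)` with 95% Wald intervals; crude ORs come
from 2×2 tables with the Woolf CI `exp(ln(ad/bc) ± 1.96·√(1/a+1/b+1/c+1/d))`.

The vulnerability index keeps the Model-3 variables whose CI excludes 1 and
weights each by its percentage risk increase, `w = OR − 1` (further divided
by 100 for a binary variable that enters the map as an area-level
population percentage). With the adjusted ORs of the original analysis
(1.60 for low education; 1.01, 0.98, 1.03 for the environmental measures)
this yields

```
index = 0.006·pct_low_education + 0.01·pct_residential
      − 0.02·avg_height_pctile + 0.03·std_height_pctile
```

computed cellwise at 10-m resolution, averaged per planning unit (TPU) and
binned to a 0.1 scale unit. Validation refits the outcome on the mapped
index alone and reports the OR per 0.1-point increase.

## Worked example

Run the default synthetic pipeline (a 4 km × 4 km city at 10-m resolution,
4000 subjects, outcome effects sized like the original adjusted ORs):

```python
from geovuln import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1, out_dir="demo_out"))
for term, r in res["ors3"].items():
    star = " *" if r.significant else ""
    print(f"{term:26s} OR {r.or_point:5.2f} ({r.ci_low:.2f}, {r.ci_high:.2f}){star}")
print(res["weights"].formula())
v = res["validation"].or_per_scale_unit
print(f"validation OR per 0.1: {v.or_point:.2f} ({v.ci_low:.2f}, {v.ci_high:.2f})")
```

prints (abridged):

```
not_married                OR  1.42 (1.06, 1.90) *
low_education              OR  1.51 (1.18, 1.95) *
avg_build_height_pctile    OR  0.98 (0.97, 0.99) *
std_build_height_pctile    OR  1.03 (1.02, 1.04) *
...
0.0051*low_education - 0.02*avg_build_height_pctile + 0.03*std_build_height_pctile
validation OR per 0.1: 1.09 (1.06, 1.12)
```

Reading: in this synthetic city the fitted Model 3 recovers effects close
to the generator's truth (low education OR 1.51 vs true 1.60; height
percentile ORs 0.98/1.03 exactly on target); the derived index weights each
retained variable by its risk increase; and subjects living in
higher-index cells carry significantly higher depression odds — a 0.1-point
increase of the index corresponds to a 9% odds increase here. The run also
writes `vuln_index.asc` (the index surface), `tpu_index.geojson` (per-zone
means binned to 0.1) and `fit.json` under `demo_out/`.

The same stages are available from the shell:

```
geovuln simulate --seed 1 --out city/
geovuln extract --cohort city/cohort.csv --rasters city/ --out features.csv
geovuln fit --features features.csv --model 3 --out fit.json
geovuln index --fit fit.json --rasters city/ --tpus city/tpu.geojson --out out/
geovuln crude --table 72,292,460,3106     # -> OR 1.66 (1.26, 2.19) *
```

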