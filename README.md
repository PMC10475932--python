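# nirscal

Chemometric calibration tools for near-infrared reflectance spectroscopy
(NIRS) of plant tissue and horticultural growing media, plus a
single-extraction companion method for fast nutrient screening.

## The problem

Closed soilless cultivation leaves two nutrient pools at crop
termination: the above-ground biomass and the spent growing medium.
Quantifying total N, P, K, Ca and Mg (and OM, pH, EC, C/N, C/P for
substrates) by wet chemistry is slow and expensive; NIRS of dried,
ground samples and a buffered ammonium-acetate (AmAc) extraction are two
fast, cheap alternatives — provided their calibrations are built and
validated carefully. `nirscal` implements that desk-side machinery:

* **Preprocessing** — standard normal variate (SNV) scatter correction,
  polynomial detrend, and gap-segment derivatives encoded by the
  four-number math-treatment code `d,g,s,s2` (e.g. `2,8,6,1`: second
  derivative, 8 nm gap, 6-point smooth, no second smooth).
* **Modified PLS (MPLS)** — NIPALS PLS1 with per-factor standardisation
  of the spectral residuals, cross-validated term selection
  (cyclically formed groups), and the two-round global-H (Mahalanobis,
  GH > 3) spectral-outlier protocol: remove in round 1, report-only in
  round 2.
* **Validation statistics** — SEC, SECV, SEP, bias, SEP(C), slope, R²
  and RPD (SD/SEP), with the exact denominator conventions:
  SEP² = bias² + (N−1)/N·SEP(C)², SEC = √(Σe²/(N−t−1)), SECV and SEP on
  the N denominator. Accuracy is read off the validation slope,
  precision off R².
* **AmAc screening** — sqrt-scale OLS calibration
  √(total) = a·√(extractable) + b on a g/L-substrate basis (dry-matter
  contents converted via the dry bulk density), with back-transformed
  validation.
* **Synthetic data** — a generator that emulates the statistical
  structure of a 369-sample strawberry-leaf dataset and a 567-sample
  growing-media dataset (published means, SDs, ranges and pinned
  correlations; Beer–Lambert band mixtures on the 400–2500 nm × 0.5 nm
  grid; duplicate scans with multiplicative/additive scatter, tilt and
  noise), so the entire pipeline is testable without instrument data.

## Worked example

```python
import nirscal as nc
from nirscal.workflow import calibrate_all, validate_constituent

cfg = nc.leaf_config(seed=7)                      # 369-sample leaf preset
ds = nc.split_calibration_validation(nc.generate_dataset(cfg), 75/369, seed=8)
cal, val = ds.subset("calibration"), ds.subset("validation")

res = calibrate_all(cal.spectra, cal.reference, ["K"])["K"]
print(res.report)        # N=292 mean=16289 SD=7500 R2=0.99 SEC=697 SECV=854
rep, _ = validate_constituent(res.model, val.spectra, val.reference, "K")
print(rep)               # N=75 SEP=1051 bias=-125 SEP(C)=1050 slope=0.98 R2=0.98 SD/SEP=7.8
```

The calibration removed two GH > 3 spectra in round 1 and selected six
PLS terms by five-group cyclic cross-validation. A validation R² of
0.98 with slope 0.98 and RPD (SD/SEP) of 7.8 means the model predicts
potassium (mg/kg DM) on unseen samples almost as precisely as the
reference analysis, with no systematic over- or under-prediction.

The extraction workflow mirrors it:

```python
pairs = nc.generate_amac_pairs("K", 150, seed=1)      # g/L substrate
m = nc.fit_amac(pairs["amac_g_per_L"], pairs["total_g_per_L"], "K")
# sqrt(total) = 0.93*sqrt(amac) + 1.78,  R2 = 0.97
nc.predict_total(m, 4.0)                              # ~13.4 g/L
```

The same operations are available from the shell:

```sh
nirscal simulate --preset leaf --seed 1 --out-dir runs/leaf
nirscal calibrate --spectra runs/leaf/spectra.csv --reference runs/leaf/reference.csv \
    --math-treatment 2,8,6,1 --scatter snv+detrend --out-dir runs/leaf/models
nirscal validate --model runs/leaf/models/model_K.json \
    --spectra runs/leaf/spectra.csv --reference runs/leaf/reference.csv
nirscal amac fit --pairs runs/leaf/amac.csv --element K --out runs/leaf/amac_K.json
```

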