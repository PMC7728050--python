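# spectransfer

Calibration transfer and chemometric modelling for mid-infrared (MIR)
soil spectral libraries.

## The problem

Large MIR diffuse-reflectance libraries — tens of thousands of soil
samples with absorbance spectra and laboratory reference values — make
excellent property-prediction models (organic carbon, carbonate, clay,
pH, bulk density). But those models assume the spectra they score were
acquired on the *same* spectrometer the library was built on. A second
laboratory's instrument differs in baseline, detector gain and
wavelength registration; scored naively, its spectra give biased and
noisier predictions.

`spectransfer` implements the standard remedy, **piecewise direct
standardization (PDS)**, together with everything around it that a
transfer study needs: Kennard–Stone transfer-set selection, spectral
pretreatments, global PLSR with one-sigma model selection, memory-based
learning (local weighted-average PLSR), two-step outlier screening,
evaluation statistics (R², RMSE, bias, RPIQ) and a synthetic
two-instrument spectra generator so every stage is testable without
proprietary library data.

## The core method

Let `P` and `S` be transfer-set spectra of the same samples scanned on
the primary and secondary instruments, on a common grid of N
wavenumber channels. PDS regresses each primary channel on a small
window of neighbouring secondary channels: for channel *i*,

    P[:, i] ≈ b0_i + S[:, i-k : i+k+1] · b_i

with the window coefficients `b_i` (length 2k+1) estimated by
principal-component regression (window columns centered on transfer-set
means; the default is a 3-point window, k = 1, with one PC per window).
Channels within k of the grid edge cannot form a complete window and
are dropped. The collected `(b0_i, b_i)` form a banded transfer
operator: applied to any new secondary spectrum it produces a
pseudo-primary spectrum that the library's models can score. Because
each coefficient vector sees only a few channels, PDS avoids the
overfitting risk of a full-spectrum transfer matrix while still
absorbing local intensity and sub-channel wavelength distortions.

## Worked example

```python
from spectransfer import (SyntheticConfig, generate_scenario, fit_pds,
                          baseline_offset, remove_region, CO2_REGION,
                          fit_plsr, metrics)

cfg = SyntheticConfig(n_calibration=600, n_transfer=60, n_prediction=150, seed=11)
sc = generate_scenario(cfg)                      # paired two-instrument study

pds = fit_pds(sc.transfer_primary, sc.transfer_secondary)
print(pds.summary())

k, grid = pds.half_window, pds.retained_grid
trim = lambda lib: lib.with_absorbance(lib.absorbance[:, k:-k], grid=grid)
prep = lambda lib: baseline_offset(remove_region(lib, *CO2_REGION)).absorbance

model = fit_plsr(prep(trim(sc.calibration)),
                 sc.calibration_props.values_for("OC"), seed=11)

y = sc.prediction_props.values_for("OC")
for arm, lib in [("primary", trim(sc.prediction_primary)),
                 ("secondary", trim(sc.prediction_secondary)),
                 ("secondary_pds", pds.transform(sc.prediction_secondary))]:
    print(metrics(y, model.predict(prep(lib)), arm=arm).summary())
```

prints

```
Piecewise Direct Standardization
========================================
window size:        3 channels (k=1)
PCs per window:     1
transfer samples:   60
input pretreatment: raw
channels retained:  1685 of 1687
...
n=150  R2=1.000  RMSE=0.02198  bias=-0.0004065  RPIQ=171   [excellent]   # primary
n=150  R2=1.000  RMSE=0.1191   bias=-0.03594    RPIQ=31.6  [excellent]   # secondary
n=150  R2=1.000  RMSE=0.04447  bias=0.003535    RPIQ=84.7  [excellent]   # secondary_pds
```

Read: predicting organic carbon from the *untransferred* secondary
spectra costs a five-fold RMSE increase over same-instrument prediction
(0.119 vs 0.022 wt%) and introduces bias; after PDS the error drops to
0.044 wt% — most of the instrument penalty is recovered from a
60-sample transfer set.

The same study runs end to end from the shell:

```bash
spectransfer run-all --scenario smoke --seed 3 --out results/
spectransfer simulate --seed 4 --out sim/
spectransfer transfer-fit --primary sim/transfer_primary.csv \
    --secondary sim/transfer_secondary.csv --out pds.json
```

Input files are wide CSVs: an `id` column, optional property columns
(BD, CaCO3, clay, OC, pH), then one numeric wavenumber header per
channel.

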