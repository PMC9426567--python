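# mixcult

Quantitative analysis of two-member microbial cocultures, built for
plate-reader and flow-cytometry experiments in which a *salvager* strain
(able to assemble a functional cobamide cofactor from the precursor
cobinamide plus a lower ligand) is cultured with a *dependent* strain that
can only use complete cobamides. The same machinery applies to any
two-strain system read out in absorbance plus two fluorescent-protein
channels (CFP/YFP) and tracked over serial transfers by two-color flow
cytometry.

`mixcult` provides, as a tested library plus a small CLI:

* **Calibration** — fluorescence-to-absorbance conversion factors from
  single-marker control wells (slopes of linear fits in a low-OD range,
  averaged over replicates), so that each fluorescence channel becomes an
  absorbance-equivalent readout of one subpopulation.
* **Growth kinetics** — pathlength correction to bacterial units
  (1 b.u. = blank-corrected OD600 of 1), well-specific absorbance blanks
  and global fluorescence blanks, centered rolling-mean smoothing
  (window 7), and robust exponential-rate extraction by the Theil–Sen
  estimator on log abundances, restricted either to a fixed abundance band
  (1.5×10⁻² – 6×10⁻² b.u.) or to a dynamically selected exponential-phase
  window based on rolling-window rate estimates (window 19, minimum 10,
  cutoff 0.1 h⁻¹). Lag times by back-interpolation to the known inoculum;
  yields as smoothed abundance at 24 h.
* **Dose–response** — the four-parameter logistic model
  `y = y_bottom + xⁿ (y_top − y_bottom)/(xⁿ + EC50ⁿ)` fitted by nonlinear
  least squares (log₁₀ EC50 parameterisation), with t-based EC50
  confidence intervals (df = N − 4) and two-sample EC50 tests
  (df = N₁ + N₂ − 8).
* **Cytometry ratios** — fixed-threshold gating of FITC/AmCyan event
  tables into YPCN/YNCP/YNCN/YPCP classes (with a transfer-0 variant),
  salvager:dependent population ratios, transfer-specific detection limits
  from blank samples, OLS slopes of log₁₀(ratio) versus transfer, pairwise
  slope t tests (df = n₁ + n₂ − 4) and Holm–Bonferroni correction.
* **Synthetic data** — a ground-truth generator for all of the above:
  lag → exponential → saturation growth, linear channel readout with
  background, crosstalk and noise, 4PL-controlled dose panels, bivariate
  log-normal event clusters with blank contamination, and deterministic
  1:100 / 24 h serial-transfer dynamics under a shared yield cap. Every
  pipeline stage is validated by parameter recovery against this
  generator.

## Worked example

Simulate a noiseless coculture plate (salvager: 0.47 h⁻¹, no lag, CFP;
dependent: 0.40 h⁻¹, 4 h lag, YFP; 10-fold yield asymmetry) together with
its two single-marker calibration wells, and run the full pipeline:

```python
import warnings
from mixcult import ExperimentConfig
from mixcult.synthetic import ReadoutParams, StrainParams, simulate_plate, default_time_grid
from mixcult.pipeline import fit_growth

layout = {
    "A1": [StrainParams("salvager", 0.47, 0.0, 5e-3, 0.5, "CFP"),
           StrainParams("dependent", 0.40, 4.0, 5e-3, 0.05, "YFP")],
    "B1": [StrainParams("salvager", 0.47, 0.0, 1e-2, 0.5, "CFP")],
    "C1": [StrainParams("dependent", 0.40, 4.0, 1e-2, 0.05, "YFP")],
}
plate = simulate_plate(layout, ReadoutParams().ideal(), default_time_grid(), seed=1)
fits = fit_growth(plate, ExperimentConfig())
print(fits[["well", "source_channel", "strain", "rate", "lag", "yield_24h"]]
      .round(3).to_string(index=False))
```

which prints

```
well source_channel    strain  rate    lag  yield_24h
  A1           A600     total 0.450  0.980       0.55
  A1            CFP  salvager 0.470 -0.026       0.50
  A1            YFP dependent 0.400  3.978       0.05
  B1           A600     total 0.472  0.004       0.50
  B1            CFP  salvager 0.470 -0.026       0.50
  C1           A600     total 0.400  3.978       0.05
  C1            YFP dependent 0.400  3.978       0.05
```

The fluorescence channels deconvolve the mixed well A1 exactly: the
salvager's rate (0.470 h⁻¹, lag ≈ 0) and the dependent's rate (0.400 h⁻¹,
lag ≈ 4 h) are recovered to three decimals, and the 24-h yields reproduce
the 10:1 asymmetry (0.50 vs 0.05 b.u.). The absorbance channel of the
mixed well reports only the total of both subpopulations — the reason the
fluorescent markers are needed at all. With the default noise model
(`ReadoutParams()` instead of `.ideal()`), channel estimates scatter
within the ±0.025 h⁻¹ technical precision typical of such measurements.

The same stages are scriptable from a shell:

```bash
mixcult simulate --out sim --seed 1 --no-noise
mixcult growth sim/plate.csv sim/wells.json --out fits
mixcult passage --rate-a 0.47 --rate-b 0.40 --transfers 8
```

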