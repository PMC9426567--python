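# Methods

This note documents the models implemented in `mixcult`, the defaults and
the numerical choices, and what the synthetic-data validation does and
does not establish.

## Latent growth model

Each subpopulation in a well follows a three-phase trajectory in
bacterial units (b.u.; 1 b.u. = blank-corrected, pathlength-corrected
OD600 of 1):

    a(t) = a0                      for t < lag
    a(t) = a0 · exp(μ (t − lag))   until a(t) reaches the yield cap
    a(t) = yield_cap               afterwards

with per-strain rate μ (h⁻¹), lag (h), inoculum a0 (b.u.) and yield cap
(b.u.). This is deliberately the *minimal* model whose parameters are the
three quantities the analysis extracts (rate, lag, yield); no resource
dynamics, diauxie or death phase is modelled. In serial-transfer
simulations the cap is shared: growth of both strains stops simultaneously
when their summed abundance reaches the cap, reflecting a single shared
limiting resource (the carbon source).

## Readout model

Raw absorbance is `A600 = p·Σa(t) + blank`, with pathlength factor
p = 0.56 (raw OD per b.u. at 200 µL in a 96-well plate; instrument
specific and configurable). Each fluorescence channel reads
`gain · a_marked + background + crosstalk · (other channel's specific
signal)`, with defaults gain 180 (CFP) / 220 (YFP) a.u. per b.u.,
backgrounds 30/40 a.u., crosstalk 0.001 a.u. per a.u. These magnitudes are
artifact choices — the emulated experiment reports only that background
and crosstalk were small — and only their smallness matters for the
conclusions drawn from the tests. Noise is 2% multiplicative Gaussian plus
additive read noise (0.001 raw OD; 0.5 a.u. per fluorescence channel).
`ReadoutParams.noiseless()` switches off both noise terms;
`ReadoutParams.ideal()` additionally zeroes crosstalk, giving a readout
the pipeline can invert exactly — that is the setting used for
exact-recovery checks, while noisy checks use the full default model. An
optional YFP saturation flattens that channel above a configurable raw OD,
emulating the under-reading of dense cultures; it is off by default.

All randomness flows through `numpy.random.default_rng` (PCG64); one seed
reproduces any simulation bit for bit, and multi-well plates derive
per-well streams from a `SeedSequence.spawn` of the plate seed.

## Calibration

Conversion factors are fitted per (day, marker, medium, channel) from
wells containing a single marked strain: an ordinary least-squares line of
raw fluorescence versus raw A600 restricted to raw OD in [0, 0.3]
(configurable; the wider [0, 0.6] range used for display-grade
calibration is supported and tested). The fit includes an intercept, but
only the slope is used. The *stored* factor is the reciprocal of that
slope — absorbance-equivalent per a.u. — so that multiplying raw
fluorescence by the factor yields raw-absorbance equivalents; a direct
inverse regression (OD on fluorescence) is available as an alternative
orientation, and the two coincide for noiseless proportional data.
Replicate factors are averaged arithmetically; non-positive slopes are
flagged invalid and excluded with a warning.

## Growth kinetics

Processing order: convert fluorescence (mixed wells) → pathlength-correct
→ blank-subtract → smooth → truncate → estimate.

* **Blanks.** Absorbance: well-specific, the mean of the first two
  readings minus the known inoculum (default 10⁻² b.u. total per well,
  from the standard OD-10⁻¹-then-1:10 inoculation; treated as a global
  config, split equally among a well's strains for per-strain lag
  interpolation). Fluorescence: global, the grand mean of the channel over
  all wells whose cultures lack that marker. A zero-lag culture is already
  growing during the first two reads, which biases the absorbance blank
  slightly (≈2×10⁻³ h⁻¹ on the rate at 0.47 h⁻¹ with 10-min sampling);
  this is a property of the blanking rule itself, not of the
  implementation, and does not affect the fluorescence channels.
* **Smoothing.** Centered rolling mean, window 7, equal weights, windows
  truncating at the series edges down to a single point (pandas
  `rolling(center=True, min_periods=1)` semantics). Series are then cut at
  the analysis horizon (24 h default, 60 h supported).
* **Rate.** Theil–Sen estimator on ln(abundance): the median of all
  pairwise slopes (pairs with identical times excluded), intercept
  median(ln a) − slope·median(t) — `scipy.stats.theilslopes` with its
  default intercept convention, which matches that definition. Estimation
  is restricted to a window: *fixed* mode keeps points with
  1.5×10⁻² < a < 6×10⁻² b.u. (strict); *dynamic* mode keeps the contiguous
  run from the first point above 1.5×10⁻² b.u. through the latest point
  whose rolling-window rate (window 19, minimum 10 points, edge-truncated)
  exceeds 0.1 h⁻¹. Dose–response panels use fixed mode (slow-growing
  doses never reach a 0.1 h⁻¹ rolling rate); coculture and competition
  analyses use dynamic mode. Fewer than 7 in-window points set the rate to
  zero and the lag to −∞ (nongrowing).
* **Lag and yield.** Lag = (ln a0_known − intercept)/rate — the time the
  back-extrapolated fit crosses the known inoculum (base-e throughout;
  the choice of base cancels). Yield is the smoothed abundance at the
  point closest to 24 h, *not* an asymptote.

## Dose–response

The four-parameter logistic curve
y = y_bottom + xⁿ(y_top − y_bottom)/(xⁿ + EC50ⁿ), with y(0) = y_bottom by
continuity. Fitting uses `scipy.optimize.curve_fit` on (y_bottom, y_top,
n, log₁₀ EC50) — the log parameterisation conditions the problem across
the decade-spanning dose grids. Replicates are averaged per dose before
fitting (per-point fitting is available). Initialisation is deterministic:
plateaus from the extreme-dose responses, n = 1, EC50 at the dose nearest
the half-range crossing. SE(EC50) comes from the delta method,
ln(10)·EC50·SE(log₁₀EC50). Confidence intervals use
t(N − 4); two-fit comparisons use t = ΔEC50/√(SE₁² + SE₂²) with
N₁ + N₂ − 8 degrees of freedom. Degenerate inputs (all-equal responses,
fewer than 4 points, fewer than 2 positive doses) raise an
unidentifiability error rather than returning garbage; non-convergence is
flagged on the returned fit.

## Cytometry

Gate classes (strict inequalities, a.u.): YPCN if FITC > 10³ and
AmCyan < 4×10³; YNCP if FITC < 7×10² and AmCyan > 2×10³; YNCN if
FITC < 10³ and AmCyan < 2×10³; YPCP otherwise. The three explicit gates
are mutually disjoint, so the rules partition the plane with YPCP as the
residual class; boundary equalities fall to the residual class. At
transfer 0 the YNCP/YNCN AmCyan cutoff rises to 5×10³ (freshly precultured
cells fluoresce differently). The salvager:dependent ratio is the count
ratio of the CFP-positive to the YFP-positive single-positive class under
the configured marker map (salvager = CFP by default; swapping the map
inverts the ratio exactly). YNCN and YPCP events are counted for QC but
ignored in ratios — no correction is applied. Detection limits per
transfer: lower = max(blank numerator-class events, 1)/10⁵, upper =
10⁵/max(blank denominator-class events, 1).

Competition statistics: OLS slope of log₁₀(ratio) versus transfer from
transfer 1 onward (the simplest estimator consistent with a per-culture
slope; censored ratios at or beyond the detection limits are excluded with
a warning), pairwise two-tailed t tests with df = n₁ + n₂ − 4, and
Holm–Bonferroni step-down control at α = 0.05. The Holm procedure is
implemented directly (sort ascending, reject while p₍ₖ₎ ≤ α/(m − k + 1),
stop at the first failure) and cross-checked against
`statsmodels.multipletests(method="holm")` in the tests.

## Problem sizes and validation scope

Validation runs use single plates of 1–3 wells at 10-min sampling over
24 h (145 points per trajectory), 12–13-dose panels, 20 seeded replicates
for the noisy channel-concordance study, 8-transfer competition runs at
10⁵ events per sample, and 200 Monte-Carlo replicates for the EC50
confidence-interval coverage study — sizes chosen to match the emulated
experiment while keeping every check fast enough to run routinely.

The generator emulates: multi-phase latent growth, affine channel readout
with background/crosstalk/noise, 4PL-controlled dose panels, log-normal
event clusters with blank contamination, and shared-cap serial transfers.
It does **not** emulate well-to-well or day-to-day biological variance
components, plate edge effects, evaporation, stationary-phase death or
lysis, spectral spillover needing compensation, or instrument drift.
Passing recovery tests therefore establish that the *analysis* is correct
and self-consistent under the stated readout model — not that the model
captures every feature of real plate-reader or cytometer data.

## Known limitations

* The well-specific absorbance blank assumes the first two reads predate
  appreciable growth; zero-lag fast growers violate this mildly (see
  above). Fluorescence-derived estimates are unaffected.
* Crosstalk contaminates the global fluorescence blank through the
  marker-free wells' other-channel signal; at the default 0.1% level the
  induced rate bias is ≲10⁻³ h⁻¹, well inside the ±0.025 h⁻¹ technical
  precision, but large crosstalk would require a compensation step that is
  out of scope.
* EC50 standard errors are asymptotic (Jacobian-based); the Monte-Carlo
  coverage test shows ≈94–95% empirical coverage at the default design,
  but very sparse dose grids will degrade this.
* FCS files are not read directly; events enter as plain CSV tables.
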