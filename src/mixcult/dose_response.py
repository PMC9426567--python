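"""Four-parameter logistic (4PL) dose-response fitting and EC50 inference.

The response model is

    y(x) = ybottom + x^n (ytop - ybottom) / (x^n + EC50^n)

with effector concentration x >= 0, baseline response ``ybottom`` (the
x -> 0 limit), plateau ``ytop`` (x -> infinity), Hill coefficient ``n`` and
half-maximal effective concentration ``EC50``.  Fitting is performed by
nonlinear least squares with EC50 parameterised internally as log10(EC50)
for conditioning; the EC50 standard error is recovered by the delta method.

Confidence intervals use the t-distribution with N - 4 degrees of freedom
(N fitted points, 4 parameters); two-fit EC50 comparisons use a two-tailed
t test with N1 + N2 - 8 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseParams",
    "DoseResponseFit",
    "UnidentifiableFitError",
    "four_pl",
    "fit_4pl",
    "ec50_confidence_interval",
    "compare_ec50",
]


class UnidentifiableFitError(ValueError):
    """Raised when the dose-response parameters cannot be identified."""


@dataclass(frozen=True)
class DoseResponseParams:
    ybottom: float
    ytop: float
    n: float
    ec50: float

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.n == 0:
            raise ValueError("Hill coefficient must be nonzero")


@dataclass
class DoseResponseFit:
    params: DoseResponseParams
    se: dict = field(default_factory=dict)  # per-parameter standard errors
    n_points: int = 0
    converged: bool = True
    cov: np.ndarray | None = None
    doses: np.ndarray | None = None
    responses: np.ndarray | None = None


def four_pl(x, p: DoseResponseParams):
    """Evaluate the 4PL curve at concentration(s) ``x`` (x >= 0).

    y(0) = ybottom by continuity (for n > 0).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        # w = x^n / (x^n + ec50^n), computed via the ratio for stability
        ratio = np.where(x > 0, (p.ec50 / np.where(x > 0, x, 1.0)) ** p.n, np.inf)
        w = 1.0 / (1.0 + ratio)
    y = p.ybottom + w * (p.ytop - p.ybottom)
    return y if y.ndim else float(y)


def _model(x, ybottom, ytop, n, log10_ec50):
    return four_pl(x, DoseResponseParams(ybottom, ytop, n, 10.0**log10_ec50))


def _initial_guess(doses: np.ndarray, responses: np.ndarray) -> list[float]:
    # deterministic: plateaus from the extreme-dose responses, n = 1,
    # EC50 at the dose closest to the half-range crossing
    order = np.argsort(doses)
    yb = float(responses[order[0]])
    yt = float(responses[order[-1]])
    half = 0.5 * (yb + yt)
    pos = doses > 0
    if not np.any(pos):
        raise UnidentifiableFitError("need at least one positive dose")
    idx = np.argmin(np.abs(responses[pos] - half))
    ec50_guess = float(doses[pos][idx])
    return [yb, yt, 1.0, float(np.log10(ec50_guess))]


def fit_4pl(
    doses,
    responses,
    use_means: bool = True,
    init: list[float] | None = None,
) -> DoseResponseFit:
    """Least-squares fit of the 4PL curve to (dose, response) data.

    With ``use_means`` (default) replicate responses are first averaged per
    dose level and the fit runs on the per-dose means.  Requires at least
    4 points with at least 2 distinct positive doses.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if use_means:
        uniq = np.unique(doses)
        means = np.array([responses[doses == d].mean() for d in uniq])
        doses, responses = uniq, means
    if len(doses) < 4:
        raise UnidentifiableFitError("need at least 4 points for a 4PL fit")
    if len(np.unique(doses[doses > 0])) < 2:
        raise UnidentifiableFitError("need at least 2 distinct positive doses")
    if np.ptp(responses) == 0:
        raise UnidentifiableFitError("all responses equal: EC50 unidentifiable")

    p0 = init if init is not None else _initial_guess(doses, responses)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(_model, doses, responses, p0=p0, maxfev=20000)
    except RuntimeError:
        converged = False
        popt, pcov = np.array(p0, dtype=float), np.full((4, 4), np.nan)

    ybottom, ytop, n, log10_ec50 = popt
    ec50 = 10.0**log10_ec50
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    se = {
        "ybottom": float(perr[0]),
        "ytop": float(perr[1]),
        "n": float(perr[2]),
        "log10_ec50": float(perr[3]),
        # delta method: d(EC50)/d(log10 EC50) = ln(10) * EC50
        "ec50": float(np.log(10.0) * ec50 * perr[3]),
    }
    return DoseResponseFit(
        params=DoseResponseParams(float(ybottom), float(ytop), float(n), float(ec50)),
        se=se,
        n_points=len(doses),
        converged=converged,
        cov=pcov,
        doses=doses,
        responses=responses,
    )


def ec50_confidence_interval(fit: DoseResponseFit, level: float = 0.95) -> tuple[float, float]:
    """EC50 +/- t_{level, N-4} * SE(EC50)."""
    df = fit.n_points - 4
    if df <= 0:
        raise ValueError("confidence interval undefined for N <= 4 points")
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    ec50 = fit.params.ec50
    half = tcrit * fit.se["ec50"]
    return (ec50 - half, ec50 + half)


def compare_ec50(fit1: DoseResponseFit, fit2: DoseResponseFit) -> float:
    """Two-tailed t test of H0: identical EC50; df = N1 + N2 - 8."""
    d = fit1.params.ec50 - fit2.params.ec50
    pooled = float(np.hypot(fit1.se["ec50"], fit2.se["ec50"]))
    df = fit1.n_points + fit2.n_points - 8
    if df <= 0:
        raise ValueError("not enough points for an EC50 comparison")
    if pooled == 0.0:
        if d == 0.0:
            return 1.0
        warnings.warn("zero pooled SE with different EC50 estimates; p set to 0")
        return 0.0
    t = d / pooled
    return float(2.0 * stats.t.sf(abs(t), df))
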