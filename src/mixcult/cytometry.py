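"""Two-color flow-cytometry gating, population ratios and competition stats.

Events carrying per-event FITC (YFP) and AmCyan (CFP) intensities are
classified into four mutually exclusive classes:

* YPCN  (YFP-positive, CFP-negative)
* YNCP  (YFP-negative, CFP-positive)
* YNCN  (YFP-negative, CFP-negative)
* YPCP  (the residual class)

using fixed intensity thresholds (strict inequalities; boundary equalities
fall into the residual class).  Transfer 0 uses a raised AmCyan cutoff
because freshly precultured cells fluoresce differently from
stationary-phase cells.  Population ratios (salvager:dependent) are event
count ratios of the two single-positive classes; transfer-specific
detection limits come from the single-positive event counts in blank
samples.  Long-term competition is summarised by the OLS slope of
log10(ratio) versus transfer, compared pairwise with two-tailed t tests
under Holm-Bonferroni control of the family-wise error rate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateScheme",
    "STANDARD_SCHEME",
    "TRANSFER_ZERO_SCHEME",
    "gate_event",
    "gate_events",
    "count_classes",
    "population_ratio",
    "detection_limits",
    "ratios_from_events",
    "ratio_slope",
    "compare_slopes",
    "pairwise_slope_tests",
    "holm_bonferroni",
    "SlopeFit",
]

CLASSES = ("YPCN", "YNCP", "YNCN", "YPCP")


@dataclass(frozen=True)
class GateScheme:
    """Intensity thresholds (a.u.) for the four gate classes."""

    ypcn_fitc_min: float = 1e3
    ypcn_amcyan_max: float = 4e3
    yncp_fitc_max: float = 7e2
    yncp_amcyan_min: float = 2e3
    yncn_fitc_max: float = 1e3
    yncn_amcyan_max: float = 2e3
    variant: str = "standard"


STANDARD_SCHEME = GateScheme()
#: transfer 0: precultured cells need a raised AmCyan cutoff
TRANSFER_ZERO_SCHEME = GateScheme(
    yncp_amcyan_min=5e3, yncn_amcyan_max=5e3, variant="transfer_zero"
)


def gate_events(fitc, amcyan, scheme: GateScheme = STANDARD_SCHEME) -> np.ndarray:
    """Classify events; returns an array of class labels.

    Rules use strict inequalities; anything matching none of the three
    explicit gates is YPCP (the residual class).
    """
    fitc = np.asarray(fitc, dtype=float)
    amcyan = np.asarray(amcyan, dtype=float)
    if not (np.all(np.isfinite(fitc)) and np.all(np.isfinite(amcyan))):
        raise ValueError("event intensities must be finite")
    labels = np.full(fitc.shape, "YPCP", dtype=object)
    ypcn = (fitc > scheme.ypcn_fitc_min) & (amcyan < scheme.ypcn_amcyan_max)
    yncp = (fitc < scheme.yncp_fitc_max) & (amcyan > scheme.yncp_amcyan_min)
    yncn = (fitc < scheme.yncn_fitc_max) & (amcyan < scheme.yncn_amcyan_max)
    labels[ypcn] = "YPCN"
    labels[yncp] = "YNCP"
    labels[yncn] = "YNCN"
    return labels


def gate_event(fitc: float, amcyan: float, scheme: GateScheme = STANDARD_SCHEME) -> str:
    return str(gate_events([fitc], [amcyan], scheme)[0])


def count_classes(fitc, amcyan, scheme: GateScheme = STANDARD_SCHEME) -> dict:
    labels = gate_events(fitc, amcyan, scheme)
    return {c: int(np.sum(labels == c)) for c in CLASSES}


def _ratio_classes(marker_map: dict) -> tuple[str, str]:
    """Gate classes for the (numerator, denominator) of the Sal:Dep ratio."""
    by_marker = {"CFP": "YNCP", "YFP": "YPCN"}
    num = by_marker[marker_map["salvager"]]
    den = by_marker[marker_map["dependent"]]
    if num == den:
        raise ValueError("salvager and dependent must carry different markers")
    return num, den


def population_ratio(
    counts: dict, marker_map: dict | None = None
) -> tuple[float, str | None]:
    """Salvager:dependent ratio of single-positive event counts.

    ``marker_map`` assigns markers to roles, e.g. {"salvager": "CFP",
    "dependent": "YFP"} (the default).  Returns (ratio, censoring flag):
    flag "upper" for a zero denominator (ratio +inf), "lower" for a zero
    numerator (ratio 0), else None.
    """
    marker_map = marker_map or {"salvager": "CFP", "dependent": "YFP"}
    num_cls, den_cls = _ratio_classes(marker_map)
    num, den = counts[num_cls], counts[den_cls]
    if den == 0:
        return np.inf, "upper"
    if num == 0:
        return 0.0, "lower"
    return num / den, None


def detection_limits(
    blank_counts: dict,
    total_events: int = 100_000,
    marker_map: dict | None = None,
) -> tuple[float, float]:
    """Transfer-specific dynamic range of the ratio estimate.

    lower = max(blank numerator-class events, 1) / total_events;
    upper = total_events / max(blank denominator-class events, 1).
    """
    marker_map = marker_map or {"salvager": "CFP", "dependent": "YFP"}
    num_cls, den_cls = _ratio_classes(marker_map)
    lower = max(blank_counts.get(num_cls, 0), 1) / total_events
    upper = total_events / max(blank_counts.get(den_cls, 0), 1)
    return float(lower), float(upper)


def ratios_from_events(
    events: pd.DataFrame,
    marker_map: dict | None = None,
    total_events: int = 100_000,
    transfer_zero_scheme: GateScheme = TRANSFER_ZERO_SCHEME,
    scheme: GateScheme = STANDARD_SCHEME,
) -> pd.DataFrame:
    """Per-transfer ratio trajectory with detection limits from blanks.

    ``events`` columns: sample_id, transfer, is_blank, FITC, AmCyan.
    Blank rows set that transfer's detection limits; sample rows produce
    one ratio per (sample_id, transfer).  Ratios at or beyond the limits
    are flagged censored.
    """
    required = {"sample_id", "transfer", "is_blank", "FITC", "AmCyan"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    rows = []
    for transfer, sub in events.groupby("transfer"):
        sch = transfer_zero_scheme if transfer == 0 else scheme
        blanks = sub[sub["is_blank"]]
        if len(blanks):
            bc = count_classes(blanks["FITC"], blanks["AmCyan"], sch)
            lower, upper = detection_limits(bc, total_events, marker_map)
        else:
            lower, upper = np.nan, np.nan
        for sample_id, s in sub[~sub["is_blank"]].groupby("sample_id"):
            counts = count_classes(s["FITC"], s["AmCyan"], sch)
            ratio, flag = population_ratio(counts, marker_map)
            censored = flag is not None
            if not censored and np.isfinite(lower):
                censored = not (lower < ratio < upper)
            rows.append(
                {
                    "sample_id": sample_id,
                    "transfer": int(transfer),
                    "ratio": ratio,
                    "lower_limit": lower,
                    "upper_limit": upper,
                    "censored": bool(censored),
                    **{f"n_{c}": counts[c] for c in CLASSES},
                }
            )
    return pd.DataFrame(rows).sort_values(["sample_id", "transfer"]).reset_index(drop=True)


@dataclass
class SlopeFit:
    slope: float  # log10(ratio) per transfer
    se: float
    intercept: float
    n_points: int


def ratio_slope(trajectory: pd.DataFrame, from_transfer: int = 1) -> SlopeFit:
    """OLS slope of log10(ratio) versus transfer index, from ``from_transfer`` on.

    Censored points (at or beyond the detection limits) are excluded with a
    warning; fewer than 3 usable transfers is an error.
    """
    sub = trajectory[trajectory["transfer"] >= from_transfer]
    if "censored" in sub.columns and sub["censored"].any():
        warnings.warn(f"excluding {int(sub['censored'].sum())} censored transfer(s) from slope fit")
        sub = sub[~sub["censored"]]
    sub = sub[np.isfinite(sub["ratio"]) & (sub["ratio"] > 0)]
    if len(sub) < 3:
        raise ValueError("need >=3 uncensored transfers for a slope estimate")
    res = stats.linregress(sub["transfer"].to_numpy(float), np.log10(sub["ratio"].to_numpy(float)))
    return SlopeFit(
        slope=float(res.slope),
        se=float(res.stderr),
        intercept=float(res.intercept),
        n_points=len(sub),
    )


def compare_slopes(fit1: SlopeFit, fit2: SlopeFit) -> float:
    """Two-tailed t test of H0: identical slopes; df = n1 + n2 - 4."""
    df = fit1.n_points + fit2.n_points - 4
    if df <= 0:
        raise ValueError("not enough points for a slope comparison")
    pooled = float(np.hypot(fit1.se, fit2.se))
    d = fit1.slope - fit2.slope
    if pooled == 0.0:
        if d == 0.0:
            return 1.0
        warnings.warn("zero pooled SE with different slopes; p set to 0")
        return 0.0
    t = d / pooled
    return float(2.0 * stats.t.sf(abs(t), df))


def pairwise_slope_tests(slopes: list[SlopeFit], alpha: float = 0.05) -> pd.DataFrame:
    """All C(n, 2) pairwise slope comparisons with Holm-Bonferroni decisions."""
    pairs = list(itertools.combinations(range(len(slopes)), 2))
    pvals = [compare_slopes(slopes[i], slopes[j]) for i, j in pairs]
    reject = holm_bonferroni(pvals, alpha) if pairs else np.array([], dtype=bool)
    return pd.DataFrame(
        {
            "i": [i for i, _ in pairs],
            "j": [j for _, j in pairs],
            "slope_i": [slopes[i].slope for i, _ in pairs],
            "slope_j": [slopes[j].slope for _, j in pairs],
            "p_value": pvals,
            "reject": reject,
        }
    )


def holm_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down decisions at family-wise level ``alpha``.

    Sort p-values ascending and reject the k-th smallest while
    p_(k) <= alpha / (m - k + 1), stopping at the first failure; decisions
    are returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order):  # k = 0 .. m-1
        if p[idx] <= alpha / (m - k):
            reject[idx] = True
        else:
            break
    return reject
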