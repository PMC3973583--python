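"""Dose-response summaries and LC50 estimation by a log-linear trendline.

Survival-to-adulthood assays place cohorts of larvae in vials of food dosed
with toxin at a series of concentrations (here: micrograms of toxin per gram
of food).  Per-concentration survival is summarized as the mean of vial-level
survival fractions with its standard error, and the LC50 — the concentration
at which half the larvae survive — is obtained the spreadsheet way: an
ordinary least-squares fit of survival fraction against ln(concentration)
(a "logarithmic trendline", zero-dose vials excluded), solved at survival
0.5, i.e. LC50 = exp((0.5 - b)/a).

The zero-dose vials are not wasted: experiments whose zero-concentration
survival falls below 80% are flagged as failing QC, since high baseline
mortality confounds the toxin effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["summarize_survival", "fit_log_trend", "resistance_ratio", "Lc50Fit", "qc_zero_dose"]

ZERO_DOSE_QC_THRESHOLD = 0.80


@dataclass
class Lc50Fit:
    """Result of the log-linear survival fit: survival = a*ln(C) + b."""

    slope: float
    intercept: float
    lc50: float
    summary: pd.DataFrame = field(repr=False)  # per-concentration mean & s.e.m.


def _check(data: pd.DataFrame) -> pd.DataFrame:
    req = {"concentration", "survivors", "total"}
    if not req.issubset(data.columns):
        raise ValueError(f"dose-response data needs columns {sorted(req)}")
    if (data["total"] <= 0).any():
        raise ValueError("every vial must contain at least one larva")
    if ((data["survivors"] < 0) | (data["survivors"] > data["total"])).any():
        raise ValueError("survivors must lie in [0, total]")
    if (data["concentration"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    return data


def summarize_survival(data: pd.DataFrame) -> pd.DataFrame:
    """Per-concentration mean and s.e.m. of vial-level survival fractions.

    s.e.m. = sample standard deviation (ddof=1) of the vial fractions divided
    by sqrt(number of vials); a single vial yields s.e.m. 0.
    """
    data = _check(data)
    frac = data["survivors"] / data["total"]
    grouped = frac.groupby(data["concentration"])
    out = pd.DataFrame(
        {
            "mean_survival": grouped.mean(),
            "sem": grouped.apply(lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0),
            "n_vials": grouped.size(),
        }
    )
    out.index.name = "concentration"
    return out.reset_index()


def qc_zero_dose(data: pd.DataFrame, threshold: float = ZERO_DOSE_QC_THRESHOLD) -> bool:
    """True when zero-concentration survival is at least ``threshold``.

    Experiments lacking zero-dose vials pass vacuously.
    """
    data = _check(data)
    zero = data[data["concentration"] == 0]
    if zero.empty:
        return True
    return float(zero["survivors"].sum() / zero["total"].sum()) >= threshold


def fit_log_trend(data: pd.DataFrame) -> Lc50Fit:
    """Fit survival = a*ln(C) + b on per-concentration means and solve LC50.

    Zero-dose points are excluded (ln 0 undefined); at least two distinct
    positive concentrations are required.  A non-negative slope means the
    response is not monotone decreasing and is an error, as is an LC50
    extrapolated beyond a decade outside the tested range.
    """
    summary = summarize_survival(data)
    pos = summary[summary["concentration"] > 0]
    if pos["concentration"].nunique() < 2:
        raise ValueError("need at least 2 distinct positive concentrations")
    x = np.log(pos["concentration"].to_numpy(dtype=float))
    y = pos["mean_survival"].to_numpy(dtype=float)
    a, b = np.polyfit(x, y, 1)
    if a >= 0:
        raise ValueError("non-monotone dose response: fitted slope is not negative")
    lc50 = float(np.exp((0.5 - b) / a))
    lo, hi = pos["concentration"].min() / 10, pos["concentration"].max() * 10
    if not lo <= lc50 <= hi:
        raise ValueError(
            f"LC50 {lc50:.3g} falls outside the credible range [{lo:.3g}, {hi:.3g}]"
        )
    return Lc50Fit(slope=float(a), intercept=float(b), lc50=lc50, summary=summary)


def resistance_ratio(lc50_a: float, lc50_b: float) -> float:
    """Fold difference in LC50 between two stocks (a over b)."""
    if lc50_a <= 0 or lc50_b <= 0:
        raise ValueError("LC50 values must be positive")
    return lc50_a / lc50_b
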