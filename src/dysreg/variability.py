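"""Per-patient biomarker variability: means, log10 coefficients of variation.

The unit of analysis is one patient's measurement series for one biomarker
over a calendar window (month or year).  Variability is the population
coefficient of variation, CV = SD/mean with the n-divisor SD, reported on a
log10 scale (LCV).  Series with zero variance have no defined LCV and are
treated as degenerate.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateSeriesError",
    "LcvResult",
    "lcv",
    "aggregate",
    "eligibility_filter",
    "paired_month_test",
    "ks_normality",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series has zero variance (LCV = log10(0) is undefined)."""


class LcvResult(NamedTuple):
    M: float
    CV: float
    LCV: float


def lcv(values: Iterable[float]) -> LcvResult:
    """Mean, population CV, and log10 CV of a measurement series.

    The SD uses the n divisor (population convention), so e.g. the series
    {0, 1} has SD exactly 0.5.  CV is scale invariant: rescaling the series
    by any positive constant leaves CV and LCV unchanged.

    Raises
    ------
    ValueError
        On fewer than 2 values, non-finite values, or mean <= 0.
    DegenerateSeriesError
        On zero variance (all values equal), where LCV is undefined.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 values to compute a CV, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    m = float(x.mean())
    if m <= 0:
        raise ValueError(f"series mean must be positive, got {m}")
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        raise DegenerateSeriesError("zero-variance series: LCV undefined")
    cv = sd / m
    return LcvResult(M=m, CV=cv, LCV=float(np.log10(cv)))


def _window_key(dates: pd.Series, window: str) -> pd.Series:
    d = pd.to_datetime(dates)
    if window == "month":
        return d.dt.strftime("%Y-%m")
    if window == "year":
        return d.dt.year.astype(str)
    raise ValueError(f"window must be 'month' or 'year', got {window!r}")


def aggregate(records: pd.DataFrame, window: Literal["month", "year"] = "year") -> pd.DataFrame:
    """Aggregate long-format records into per patient x biomarker x window summaries.

    Parameters
    ----------
    records : DataFrame with columns patient_id, date, biomarker, value.
    window : "month" for calendar months, "year" for calendar years.

    Returns
    -------
    DataFrame with columns patient_id, biomarker, window, M, CV, LCV.
    Windows with fewer than 2 measurements, or zero variance, are omitted
    with a logged warning.
    """
    required = {"patient_id", "date", "biomarker", "value"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"records missing columns: {sorted(missing)}")
    df = records[["patient_id", "biomarker", "value"]].copy()
    df["window"] = _window_key(records["date"], window)
    df["value"] = df["value"].astype(float)
    df["value_sq"] = df["value"] ** 2
    g = df.groupby(["patient_id", "biomarker", "window"], sort=True)
    agg = g.agg(n=("value", "size"), M=("value", "mean"), msq=("value_sq", "mean"))
    # population SD (n divisor) via E[x^2] - E[x]^2
    agg["SD"] = np.sqrt(np.maximum(agg["msq"] - agg["M"] ** 2, 0.0))
    ok = (agg["n"] >= 2) & (agg["SD"] > 0) & (agg["M"] > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning(
            "aggregate(window=%s): omitted %d windows with <2 measurements, "
            "zero variance, or non-positive mean",
            window,
            n_skipped,
        )
    agg = agg.loc[ok]
    out = agg.reset_index()[["patient_id", "biomarker", "window", "M"]].copy()
    out["CV"] = (agg["SD"] / agg["M"]).to_numpy()
    out["LCV"] = np.log10(out["CV"].to_numpy())
    return out


def eligibility_filter(metadata: pd.DataFrame, records: pd.DataFrame | None = None) -> pd.Index:
    """Apply cohort eligibility rules and return the included patient ids.

    A patient is eligible when, over the observation year, they had strictly
    more than 100 dialysis sessions, strictly more than 21 of the 24
    scheduled blood tests, and a treatment vintage of at least 0.5 years at
    the window start.
    """
    for field in ("n_sessions", "n_blood_tests", "vintage_years"):
        if field not in metadata.columns:
            raise KeyError(f"metadata missing required field: {field!r}")
    keep = (
        (metadata["n_sessions"] > 100)
        & (metadata["n_blood_tests"] > 21)
        & (metadata["vintage_years"] >= 0.5)
    )
    included = metadata.index[keep]
    logger.info("eligibility_filter: %d of %d patients included", keep.sum(), len(metadata))
    return included


def paired_month_test(
    summaries: pd.DataFrame,
    month_a: str,
    month_b: str,
    quantity: Literal["M", "LCV"] = "M",
) -> tuple[float, float, dict]:
    """Two-sided paired t-test comparing a quantity between two calendar months.

    Only patients with summaries in both months enter the comparison
    (e.g. winter-vs-summer blood pressure).  Returns (t, p, means) where
    means maps each month to its (mean, SD, n) over the paired patients.
    """
    if quantity not in ("M", "LCV"):
        raise ValueError(f"quantity must be 'M' or 'LCV', got {quantity!r}")
    a = summaries.loc[summaries["window"] == month_a].set_index("patient_id")[quantity]
    b = summaries.loc[summaries["window"] == month_b].set_index("patient_id")[quantity]
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 patients with both months, got {len(shared)} "
            f"for {month_a!r} vs {month_b!r}"
        )
    xa, xb = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    diff = xa - xb
    if np.allclose(diff, diff[0]) and diff.std(ddof=1) == 0:
        if diff[0] == 0:
            # identical vectors: no difference at all
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero-variance differences: paired t-test undefined")
    else:
        t, p = stats.ttest_rel(xa, xb)
    means = {
        month_a: (float(xa.mean()), float(xa.std(ddof=1)), len(shared)),
        month_b: (float(xb.mean()), float(xb.std(ddof=1)), len(shared)),
    }
    return float(t), float(p), means


def ks_normality(values: Iterable[float], alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sample Kolmogorov-Smirnov test against N(mean, sd) fit to the sample.

    Parameters are estimated from the same sample, which makes the test
    conservative (the classical KS null distribution is used, not a
    Lilliefors correction); adequate for flagging grossly non-normal
    variables before correlation-method selection.

    Returns (statistic, p, rejected_at_alpha).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 8:
        raise ValueError(f"need >= 8 values for the KS test, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input: KS normality test undefined")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p), bool(p < alpha)
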