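"""Descriptive layer: per-analyte summary statistics, the 2×IQR outlier rule,
composition percentages and guideline-exceedance tables."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ConcentrationPanel

__all__ = [
    "MetalSummary",
    "summarize_analyte",
    "summarize_panel",
    "iqr_outlier_flag",
    "composition_shares",
    "threshold_exceedance",
]

#: Quartile conventions exposed to callers, mapped to numpy interpolation
#: methods.  "inclusive" is linear interpolation between order statistics at
#: position p(n−1)+1 — the spreadsheet convention — and the default.
QUARTILE_METHODS = {
    "inclusive": "linear",
    "exclusive": "weibull",
    "nearest": "nearest",
    "lower": "lower",
    "higher": "higher",
    "midpoint": "midpoint",
}


@dataclass(frozen=True)
class MetalSummary:
    """Summary statistics for one analyte across brands (all in μg/L)."""

    analyte: str
    n: int
    sum: float
    mean: float
    sd: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    iqr: float
    quartile_method: str = "inclusive"

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_analyte(
    values: Sequence[float] | np.ndarray,
    analyte: str = "",
    quartile_method: str = "inclusive",
) -> MetalSummary:
    """Sum, mean, sample SD, extrema, quartiles and IQR of one analyte.

    IQR = Q3 − Q1 with quartiles under the configured interpolation
    convention; SD uses the n−1 denominator (0 for a singleton).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if np.any(x < 0):
        raise ValueError("levels must be non-negative")
    method = QUARTILE_METHODS[quartile_method]
    q1, med, q3 = np.percentile(x, [25, 50, 75], method=method)
    return MetalSummary(
        analyte=analyte,
        n=int(x.size),
        sum=float(x.sum()),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        minimum=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(x.max()),
        iqr=float(q3 - q1),
        quartile_method=quartile_method,
    )


def summarize_panel(
    panel: ConcentrationPanel,
    analytes: Sequence[str] | None = None,
    quartile_method: str = "inclusive",
) -> pd.DataFrame:
    """Summary table (one row per analyte) in the conventional column layout
    Sum, mean, SD, minimum, Q1, Median, Q3, maximum, IQR, sorted by Sum
    descending."""
    analytes = list(analytes) if analytes is not None else panel.metals()
    rows = []
    for a in analytes:
        s = summarize_analyte(panel.levels[a].to_numpy(), a, quartile_method)
        rows.append({
            "analyte": a, "Sum": s.sum, "mean": s.mean, "SD": s.sd,
            "minimum": s.minimum, "Q1": s.q1, "Median": s.median,
            "Q3": s.q3, "maximum": s.maximum, "IQR": s.iqr,
        })
    df = pd.DataFrame(rows).set_index("analyte")
    return df.sort_values("Sum", ascending=False)


def iqr_outlier_flag(mean: float, iqr: float) -> bool:
    """True iff the mean strictly exceeds twice the interquartile range.

    A mean that large relative to the central spread signals a distribution
    dominated by a few extreme brands (the copper pattern in artisanal
    spirits).
    """
    if iqr < 0:
        raise ValueError("IQR cannot be negative")
    return mean > 2.0 * iqr


def composition_shares(panel: ConcentrationPanel,
                       analytes: Sequence[str] | None = None) -> dict:
    """Per-brand and grand-total composition percentages.

    ``brand_shares``: share of each analyte within its brand's total (rows
    sum to 100).  ``grand_shares``: each cell as a share of the sum over all
    cells.  ``analyte_grand_shares``: each analyte's total as a share of the
    grand total.  Brands whose total is zero are reported in
    ``undefined_brands`` and carry NaN shares rather than zeros.
    """
    analytes = list(analytes) if analytes is not None else panel.metals()
    lv = panel.levels[analytes].astype(float)
    if not (lv.to_numpy() > 0).any():
        raise ValueError("composition shares need at least one positive level")
    brand_tot = lv.sum(axis=1)
    grand_tot = float(lv.to_numpy().sum())
    undefined = brand_tot.index[brand_tot == 0].tolist()
    denom = brand_tot.replace(0, np.nan)
    brand_shares = lv.div(denom, axis=0) * 100.0
    grand_shares = lv / grand_tot * 100.0
    analyte_grand = lv.sum(axis=0) / grand_tot * 100.0
    return {
        "brand_shares": brand_shares,
        "grand_shares": grand_shares,
        "analyte_grand_shares": analyte_grand,
        "brand_totals": brand_tot,
        "grand_total": grand_tot,
        "undefined_brands": undefined,
    }


def threshold_exceedance(
    panel: ConcentrationPanel,
    limits: Mapping[str, float],
) -> pd.DataFrame:
    """Percent by which each level exceeds a per-analyte guideline.

    Returns a long table (brand, analyte, level, limit, pct_above,
    within_limit); ``pct_above`` is (level − limit)/limit × 100 where
    positive, else 0 with ``within_limit`` True.  Analytes without a limit
    are skipped (they appear in the returned frame's attrs under
    ``skipped``).
    """
    rows = []
    skipped = []
    for a, lim in limits.items():
        if a not in panel.analyte_ids:
            skipped.append(a)
            continue
        if lim <= 0:
            raise ValueError(f"guideline limit for {a} must be positive")
        for b in panel.brand_ids:
            lvl = float(panel.levels.at[b, a])
            pct = (lvl - lim) / lim * 100.0
            rows.append({
                "brand": b, "analyte": a, "level": lvl, "limit": lim,
                "pct_above": max(pct, 0.0), "within_limit": lvl <= lim,
            })
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df
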