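"""The risk engine: average daily intake (ADI), target hazard quotients
(THQ), hazard indices (HI), "1-in-x" risk ratios and incremental lifetime
carcinogenic risk (CR).

Model
-----
For a contaminant at concentration Mc (mg per kg of drink) the chronic
average daily intake is

    ADI = Mc × IR × CF × EF × ED / (BW × ATn)            [mg/kg·day]

with IR the ingestion rate (g/day), CF = 10⁻³ the g→kg conversion, EF the
exposure frequency (day/year), ED the exposure duration (year), BW the body
weight (kg) and ATn the averaging time (day).  Non-carcinogenic risk is the
target hazard quotient THQ = ADI/RfD against the oral reference dose, and the
hazard index HI of a drink is the sum of its analytes' THQs under an additive
mixture assumption: HI < 1 is safe, 1 ≤ HI < 5 a level of concern, HI ≥ 5
high.  Carcinogenic risk is CR = Σ ADI × CSF over the analytes with a cancer
slope factor, read as a lifetime excess cancer probability; 1/CR is the
number of consumers per expected case.

Ethanol is treated as an analyte of its own.  Its concentration enters as a
mass fraction, Mc = abv/100 × 10⁶ mg/kg (equating %w/w with %v/v), the
convention that reproduces the published intake arithmetic; a strict pathway
that keeps the ingestion rate as drink mass instead of ethanol mass is also
available (mode ``strict``), and yields ≈2.5× larger ethanol intakes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ETHANOL,
    ConcentrationPanel,
    ExposureProfile,
    ToxicityReference,
)

__all__ = [
    "ethanol_mc",
    "ingestion_rate",
    "average_daily_intake",
    "target_hazard_quotient",
    "row_percent_transform",
    "hazard_index",
    "hazard_category",
    "ratio_string",
    "persons_per_case",
    "carcinogenic_risk",
    "panel_mc",
    "adi_table",
    "thq_table",
    "RiskTable",
    "compute_risk_table",
]

#: HI interpretation bands (right-open).
HI_SAFE_BELOW = 1.0
HI_HIGH_FROM = 5.0


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def ethanol_mc(abv: float, convention: str = "mass_fraction") -> float:
    """Ethanol concentration Mc in mg per kg of drink from % (v/v).

    ``mass_fraction`` (default): abv% v/v is equated with abv g per 100 g of
    drink, so Mc = abv/100 × 10⁶ mg/kg (40% → 400,000).  ``table``: the
    alternative published-table reading Mc = abv × 100 mg/kg (40% → 4,000),
    kept selectable because it appears in print even though it is not
    consistent with the printed intake it accompanies.
    """
    if not 0.0 <= abv <= 100.0:
        raise ValueError("abv must lie in [0, 100] % v/v")
    if convention == "mass_fraction":
        return abv / 100.0 * 1e6
    if convention == "table":
        return abv * 100.0
    raise ValueError(f"unknown ethanol Mc convention: {convention!r}")


def ingestion_rate(
    sachets_per_day: float = 2.5,
    sachet_volume_mL: float = 100.0,
    abv: float = 40.0,
    ethanol_density_g_per_mL: float = 0.7854,
) -> float:
    """Daily ethanol-mass ingestion rate IR in g/day.

    IR = sachets/day × sachet volume × abv/100 × density of pure ethanol.
    The defaults (2.5 × 100 mL of 40% v/v spirit) give 78.54 g/day.
    """
    for name, v in (("sachets_per_day", sachets_per_day),
                    ("sachet_volume_mL", sachet_volume_mL),
                    ("ethanol_density_g_per_mL", ethanol_density_g_per_mL)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if not 0.0 <= abv <= 100.0:
        raise ValueError("abv must lie in [0, 100] % v/v")
    return sachets_per_day * sachet_volume_mL * abv / 100.0 * ethanol_density_g_per_mL


def average_daily_intake(Mc: float, profile: ExposureProfile) -> float:
    """ADI = Mc × IR × CF × EF × ED / (BW × ATn), in mg/kg·day."""
    if Mc < 0:
        raise ValueError("Mc must be non-negative")
    if profile.BW <= 0 or profile.ATn <= 0:
        raise ValueError("BW and ATn must be positive")
    return Mc * profile.IR * profile.CF * profile.EF * profile.ED / (
        profile.BW * profile.ATn)


def target_hazard_quotient(ADI: float, RfD: float | None) -> float | None:
    """THQ = ADI/RfD; ``None`` (not 0) when the analyte has no oral RfD, so
    "no reference" is never mistaken for "no risk"."""
    if RfD is None:
        return None
    if RfD <= 0:
        raise ValueError("RfD must be strictly positive")
    if ADI < 0:
        raise ValueError("ADI must be non-negative")
    return ADI / RfD


def hazard_category(HI: float) -> str:
    """safe (HI<1) | concern (1≤HI<5) | high (HI≥5)."""
    if HI < HI_SAFE_BELOW:
        return "safe"
    if HI < HI_HIGH_FROM:
        return "concern"
    return "high"


def ratio_string(HI: float) -> str:
    """Render HI as a "1 person in x" ratio: "1/x" with x = round(1/HI) for
    HI < 1, ">1" once every consumer is expected to be affected."""
    if HI < 0:
        raise ValueError("HI must be non-negative")
    if HI == 0:
        return "0"
    if HI >= 1:
        return ">1"
    return f"1/{round(1.0 / HI)}"


def persons_per_case(CR: float) -> float:
    """Number of consumers per expected lifetime cancer case, round(1/CR);
    infinite when CR is zero."""
    if CR < 0:
        raise ValueError("CR must be non-negative")
    if CR == 0:
        return math.inf
    return float(round(1.0 / CR))


# ---------------------------------------------------------------------------
# matrix-level operations
# ---------------------------------------------------------------------------

def panel_mc(panel: ConcentrationPanel, profile: ExposureProfile,
             mode: str = "published") -> pd.DataFrame:
    """Convert a panel's levels to Mc in mg per kg of drink.

    Metals: μg/L → mg/kg via 10⁻³ and the panel's drink density (default
    1 kg/L, equating μg/L with μg/kg).  Ethanol: per the profile's
    Mc_convention.  ``mode`` selects the ethanol pathway — ``published``
    evaluates the ethanol intake exactly as published (ethanol-mass IR
    together with mass-fraction Mc); ``strict`` divides the ethanol Mc by
    abv/100 so the ingestion rate is interpreted once, as drink mass.
    """
    if mode not in ("published", "strict"):
        raise ValueError(f"unknown ethanol pathway mode: {mode!r}")
    mc = panel.levels.astype(float).copy()
    for a in panel.analyte_ids:
        if a == ETHANOL:
            col = []
            for abv in mc[a]:
                m = ethanol_mc(float(abv), profile.Mc_convention)
                if mode == "strict" and abv > 0:
                    m = m / (abv / 100.0)
                col.append(m)
            mc[a] = col
        else:
            mc[a] = mc[a] * 1e-3 / panel.density_kg_per_L
    return mc


def adi_table(panel: ConcentrationPanel, profile: ExposureProfile,
              mode: str = "published") -> pd.DataFrame:
    """Brands × analytes ADI matrix in mg/kg·day."""
    mc = panel_mc(panel, profile, mode)
    scale = profile.IR * profile.CF * profile.EF * profile.ED / (
        profile.BW * profile.ATn)
    return mc * scale


def thq_table(adi: pd.DataFrame, reference: ToxicityReference) -> pd.DataFrame:
    """Brands × analytes THQ matrix; analytes without an RfD get NaN."""
    thq = pd.DataFrame(index=adi.index, columns=adi.columns, dtype=float)
    for a in adi.columns:
        rfd = reference.rfd(a)
        thq[a] = np.nan if rfd is None else adi[a] / rfd
    return thq


def row_percent_transform(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Rescale each row (or column, ``axis="columns"``) to sum to 100.

    Used on THQ matrices so a single dominant analyte (copper in artisanal
    spirits) does not swamp a clustering or display.  All-NaN or all-zero
    rows are returned as NaN ("missing"), never as zeros.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    m = matrix.astype(float)
    if axis == "columns":
        return row_percent_transform(m.T, "rows").T
    tot = m.sum(axis=1, skipna=True)
    valid = m.notna().any(axis=1) & (tot > 0)
    out = m.div(tot.where(valid), axis=0) * 100.0
    return out


def hazard_index(
    thqs: Mapping[str, float | None] | pd.Series,
    include: Sequence[str] | None = None,
) -> dict:
    """Sum per-analyte THQs of one brand into its hazard index.

    Missing THQs (no RfD) are excluded from the sum and listed, never coerced
    to zero.  Returns HI, the "1/x" ratio string, the interpretation
    category, and the analytes included/excluded.
    """
    s = pd.Series(thqs, dtype=float)
    if include is not None:
        if len(include) == 0:
            raise ValueError("empty analyte inclusion set")
        s = s.reindex(list(include))
    included = s.index[s.notna()].tolist()
    excluded = s.index[s.isna()].tolist()
    if not included:
        raise ValueError("no non-missing THQ to aggregate")
    hi = float(s.dropna().sum())
    return {
        "HI": hi,
        "ratio": ratio_string(hi),
        "category": hazard_category(hi),
        "included": included,
        "excluded_missing_rfd": excluded,
    }


def carcinogenic_risk(
    mc_by_analyte: Mapping[str, float] | pd.Series,
    profile: ExposureProfile,
    reference: ToxicityReference,
) -> dict:
    """Lifetime carcinogenic risk CR = Σ ADI × CSF over analytes with a
    cancer slope factor.

    Returns CR, persons_per_case = round(1/CR), the per-analyte risk
    contributions, and the analytes excluded for lack of a CSF.
    """
    mc = pd.Series(mc_by_analyte, dtype=float)
    contributions = {}
    excluded = []
    for a, m in mc.items():
        csf = reference.csf(a)
        if csf is None:
            excluded.append(a)
            continue
        contributions[a] = average_daily_intake(float(m), profile) * csf
    if not contributions:
        raise ValueError("no analyte with a cancer slope factor")
    cr = float(sum(contributions.values()))
    return {
        "CR": cr,
        "persons_per_case": persons_per_case(cr),
        "contributions": contributions,
        "excluded_no_csf": excluded,
    }


# ---------------------------------------------------------------------------
# full risk table
# ---------------------------------------------------------------------------

@dataclass
class RiskTable:
    """All risk quantities for one panel under one exposure profile."""

    adi: pd.DataFrame                 # brands × analytes, mg/kg·day
    thq: pd.DataFrame                 # brands × analytes, dimensionless
    thq_rowpct: pd.DataFrame          # row-percent THQ (orientation per config)
    hi: pd.DataFrame                  # per brand: HI, ratio, category (metals)
    hi_with_ethanol: pd.DataFrame     # per brand incl. ethanol when present
    analyte_hi: pd.Series             # per-analyte column sums of thq_rowpct
    cancer: pd.DataFrame              # per brand: CR, persons_per_case
    cancer_pooled: dict               # CR over the panel-mean concentrations
    config: dict = field(default_factory=dict)

    def brands_by_hi(self) -> pd.DataFrame:
        return self.hi.sort_values("HI", ascending=False)


def compute_risk_table(
    panel: ConcentrationPanel,
    profile: ExposureProfile,
    reference: ToxicityReference,
    *,
    mode: str = "published",
    row_percent_axis: str = "rows",
) -> RiskTable:
    """Run the full deterministic risk pipeline on a panel.

    Per-brand HI over the metals excludes ethanol (reported separately in
    ``hi_with_ethanol``) so the contaminant burden is visible next to the
    intoxicant's own hazard.  The pooled cancer risk uses the across-brand
    mean concentration of each CSF-bearing analyte.
    """
    adi = adi_table(panel, profile, mode)
    thq = thq_table(adi, reference)
    metals = [a for a in panel.analyte_ids if a != ETHANOL]

    thq_metals = thq[metals]
    rowpct = row_percent_transform(thq_metals, row_percent_axis)

    hi_rows, hi_eth_rows = [], []
    for b in panel.brand_ids:
        agg = hazard_index(thq_metals.loc[b])
        hi_rows.append({"brand": b, "HI": agg["HI"], "ratio": agg["ratio"],
                        "category": agg["category"],
                        "excluded_missing_rfd": ",".join(agg["excluded_missing_rfd"])})
        agg_all = hazard_index(thq.loc[b])
        hi_eth_rows.append({"brand": b, "HI": agg_all["HI"],
                            "ratio": agg_all["ratio"],
                            "category": agg_all["category"]})
    hi = pd.DataFrame(hi_rows).set_index("brand")
    hi_eth = pd.DataFrame(hi_eth_rows).set_index("brand")

    analyte_hi = rowpct.sum(axis=0, skipna=True) if row_percent_axis == "rows" \
        else rowpct.sum(axis=1, skipna=True)

    mc = panel_mc(panel, profile, mode)
    cancer_rows = []
    for b in panel.brand_ids:
        res = carcinogenic_risk(mc.loc[b, metals], profile, reference)
        cancer_rows.append({"brand": b, "CR": res["CR"],
                            "persons_per_case": res["persons_per_case"]})
    cancer = pd.DataFrame(cancer_rows).set_index("brand")
    pooled = carcinogenic_risk(mc[metals].mean(axis=0), profile, reference)

    return RiskTable(
        adi=adi, thq=thq, thq_rowpct=rowpct, hi=hi, hi_with_ethanol=hi_eth,
        analyte_hi=analyte_hi, cancer=cancer, cancer_pooled=pooled,
        config={"mode": mode, "row_percent_axis": row_percent_axis,
                "Mc_convention": profile.Mc_convention},
    )
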