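"""Synthetic concentration panels with the statistical structure of sachet /
artisanal spirit surveys, plus the in-print study fixture.

The generator emulates the features the risk pipeline has to cope with:

* right-skewed trace-metal levels (log-normal marginals, baselines calibrated
  to the published per-metal medians);
* a class of artisanally distilled brands whose copper — leached from the
  copper condensation tubing — makes up 92–100% of the brand's total metal
  burden;
* one heavily contaminated "outlier" industrial brand elevated in most
  metals simultaneously;
* duplicate-measurement noise (SD proportional to the level);
* left-censoring at per-analyte method detection limits.

Every draw is deterministic under the mandatory seed, and the ground truth
(class labels, pre-noise levels) is returned alongside the panel so planted
structure can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ETHANOL,
    METALS,
    ConcentrationPanel,
    ExposureProfile,
    ToxicityReference,
    builtin_reference,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_panel",
    "parameter_recovery_suite",
    "StudyFixture",
    "study_fixture",
    "DEFAULT_MEDIANS",
    "DEFAULT_MDLS",
]

#: Baseline per-metal medians (μg/L) the log-normal locations are calibrated
#: to; metals whose survey median rounds to zero get a near-detection-limit
#: baseline so they are present but frequently censored.
DEFAULT_MEDIANS: dict[str, float] = {
    "Cu": 3.4, "Al": 32.1, "Sr": 56.4, "Zn": 7.1, "Ba": 10.8, "Mn": 9.1,
    "Se": 0.8, "As": 0.6, "Ni": 0.7, "V": 0.03, "Cr": 0.3, "Sn": 0.5,
    "Sb": 0.6, "Pb": 0.1, "Co": 0.03, "Mo": 0.1, "Be": 0.03, "Cd": 0.03,
    "Ag": 0.03, "Tl": 0.03,
}

#: Method detection limits (μg/L), in the range of the instrument's lowest
#: calibration points.
DEFAULT_MDLS: dict[str, float] = {
    "Ag": 0.02, "Cd": 0.02, "Be": 0.05, "Cr": 0.05, "Cu": 0.05, "Pb": 0.05,
    "Sb": 0.05, "As": 0.1, "Se": 0.1, "Tl": 0.1, "Ni": 0.1, "Zn": 0.1,
    "Al": 0.05, "Ba": 0.05, "Mn": 0.05, "Mo": 0.05, "Co": 0.05, "Sn": 0.05,
    "Sr": 0.05, "V": 0.05,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic panel generator.

    ``artisanal_cu_share`` plants the artisanal copper signature directly:
    each artisanal brand's Cu level is set so that Cu's share of the brand's
    metal total is drawn uniformly from this interval.  Setting it to None
    falls back to multiplying the baseline Cu draw by ``artisanal_cu_boost``
    (useful as a tunable/negative control, but it does not pin the share).
    """

    n_industrial: int = 13
    n_artisanal: int = 4
    analytes: tuple[str, ...] = METALS + (ETHANOL,)
    medians: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MEDIANS))
    sigma: float = 0.6                       # log-scale spread of baselines
    artisanal_cu_share: tuple[float, float] | None = (0.92, 1.0)
    artisanal_cu_boost: float = 500.0
    outlier_brand: bool = True               # one REX-like industrial brand
    outlier_boost: float = 10.0
    outlier_abv: float = 20.0
    abv: float = 40.0
    duplicate_cv: float = 0.1                # duplicate-measurement CV
    mdls: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MDLS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_industrial < 0 or self.n_artisanal < 0:
            raise ValueError("brand counts must be non-negative")
        if len(self.analytes) == 0:
            raise ValueError("empty analyte list")
        if self.sigma < 0 or self.duplicate_cv < 0:
            raise ValueError("sigma and duplicate_cv must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticTruth:
    """Ground truth aligned 1-to-1 with a generated panel."""

    classes: pd.Series            # brand → industrial | artisanal | outlier
    true_levels: pd.DataFrame     # pre-noise, pre-censoring concentrations
    planted_clusters: pd.Series   # brand → 1 (non-artisanal) | 2 (artisanal)


def generate_panel(config: GeneratorConfig) -> tuple[ConcentrationPanel, SyntheticTruth]:
    """Draw one synthetic brands × analytes panel plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    metals = [a for a in cfg.analytes if a != ETHANOL]
    has_ethanol = ETHANOL in cfg.analytes

    brands, classes = [], []
    n_out = 1 if (cfg.outlier_brand and cfg.n_industrial > 0) else 0
    for i in range(cfg.n_industrial - n_out):
        brands.append(f"IND{i + 1:02d}")
        classes.append("industrial")
    if n_out:
        brands.append("OUT01")
        classes.append("outlier")
    for i in range(cfg.n_artisanal):
        brands.append(f"ART{i + 1:02d}")
        classes.append("artisanal")
    if not brands:
        raise ValueError("config produces zero brands")

    mu = np.array([math.log(cfg.medians[m]) for m in metals])
    true = np.exp(mu[None, :] + cfg.sigma * rng.standard_normal((len(brands), len(metals))))

    cls = np.array(classes)
    if n_out:
        true[cls == "outlier"] *= cfg.outlier_boost
    if metals and "Cu" in metals:
        cu_ix = metals.index("Cu")
        art_rows = np.where(cls == "artisanal")[0]
        for r in art_rows:
            if cfg.artisanal_cu_share is not None:
                lo, hi = cfg.artisanal_cu_share
                share = rng.uniform(lo, min(hi, 0.999999))
                rest = true[r].sum() - true[r, cu_ix]
                true[r, cu_ix] = share / (1.0 - share) * rest
            else:
                true[r, cu_ix] *= cfg.artisanal_cu_boost

    # duplicate-measurement noise: multiplicative, CV-scaled
    noise = np.exp(cfg.duplicate_cv * rng.standard_normal(true.shape))
    measured = true * noise
    sds = cfg.duplicate_cv * measured

    mdl = pd.Series({m: cfg.mdls.get(m, np.nan) for m in metals}, dtype=float)
    cens = measured < mdl.to_numpy()[None, :]
    levels = measured.copy()
    levels[cens] = 0.0  # default zero substitution; mask retains censoring

    lv = pd.DataFrame(levels, index=brands, columns=metals)
    sd_df = pd.DataFrame(sds, index=brands, columns=metals)
    cen_df = pd.DataFrame(cens, index=brands, columns=metals)
    true_df = pd.DataFrame(true, index=brands, columns=metals)

    if has_ethanol:
        abv = np.full(len(brands), cfg.abv)
        if n_out:
            abv[cls == "outlier"] = cfg.outlier_abv
        lv[ETHANOL] = abv
        sd_df[ETHANOL] = 0.0
        cen_df[ETHANOL] = False
        true_df[ETHANOL] = abv
        mdl[ETHANOL] = np.nan
        lv = lv[list(cfg.analytes)]
        sd_df = sd_df[list(cfg.analytes)]
        cen_df = cen_df[list(cfg.analytes)]
        true_df = true_df[list(cfg.analytes)]

    panel = ConcentrationPanel(
        levels=lv, censored=cen_df, mdl=mdl, sds=sd_df,
        provenance=[f"synthetic:seed={cfg.seed}", "nondetect:zero"],
    )
    truth = SyntheticTruth(
        classes=pd.Series(classes, index=brands, name="class"),
        true_levels=true_df,
        planted_clusters=pd.Series(
            [2 if c == "artisanal" else 1 for c in classes],
            index=brands, name="cluster"),
    )
    return panel, truth


def parameter_recovery_suite(config: GeneratorConfig, n_reps: int) -> pd.DataFrame:
    """Monte-Carlo check that the generator's log-location parameters are
    recoverable from its own output.

    For each replicate a panel is drawn and, per metal, the log-location is
    estimated as the mean log level over the *industrial, uncensored* cells
    (artisanal Cu and the outlier brand are planted shifts, not baseline).
    Reports bias, the standard error of the mean bias, 95% CI coverage of the
    true location, and the average censoring fraction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = config
    metals = [a for a in cfg.analytes if a != ETHANOL]
    estimates = {m: [] for m in metals}
    covered = {m: 0 for m in metals}
    cens_frac = {m: [] for m in metals}
    ci_count = {m: 0 for m in metals}
    for rep in range(n_reps):
        rep_cfg = GeneratorConfig(**{**cfg.__dict__, "seed": cfg.seed + rep})
        panel, truth = generate_panel(rep_cfg)
        base = truth.classes[truth.classes == "industrial"].index
        for m in metals:
            vals = panel.levels.loc[base, m]
            keep = ~panel.censored.loc[base, m]
            obs = vals[keep]
            cens_frac[m].append(1.0 - keep.mean())
            if len(obs) < 2:
                continue
            logs = np.log(obs.to_numpy())
            est = logs.mean()
            se = logs.std(ddof=1) / math.sqrt(len(logs))
            estimates[m].append(est)
            ci_count[m] += 1
            if abs(est - math.log(cfg.medians[m])) <= 1.96 * se:
                covered[m] += 1
    rows = []
    for m in metals:
        true_mu = math.log(cfg.medians[m])
        ests = np.array(estimates[m])
        if ests.size:
            bias = float(ests.mean() - true_mu)
            se_bias = float(ests.std(ddof=1) / math.sqrt(ests.size)) if ests.size > 1 else np.nan
        else:
            bias, se_bias = np.nan, np.nan
        rows.append({
            "analyte": m, "true_log_location": true_mu,
            "bias": bias, "se_bias": se_bias,
            "coverage": covered[m] / ci_count[m] if ci_count[m] else np.nan,
            "censor_fraction": float(np.mean(cens_frac[m])),
            "n_reps": int(ests.size),
        })
    return pd.DataFrame(rows).set_index("analyte")


# ---------------------------------------------------------------------------
# the in-print study fixture
# ---------------------------------------------------------------------------

_BRAND_ROWS = [
    # id, name, class, abv (% v/v)
    ("UGW", "Uganda Waragi", "industrial", 40.0),
    ("B7W", "Bond 7 Whisky", "industrial", 40.0),
    ("CW1", "Chief Waragi (gin)", "industrial", 40.0),
    ("CW2", "Chief Waragi (gin)", "industrial", 40.0),
    ("SAG", "Salongo Gin", "industrial", 40.0),
    ("ROV", "Royal Vodka", "industrial", 40.0),
    ("KPW", "Kick Gin Pineapple Waragi", "industrial", 40.0),
    ("BRG", "Brigade Gin", "industrial", 40.0),
    ("B5V", "Big 5 Vodka", "industrial", 40.0),
    ("REX", "Relax", "industrial", 20.0),
    ("GOV", "Goal Vodka", "industrial", 40.0),
    ("BEG", "Beckam Gin", "industrial", 40.0),
    ("V6T", "V6 Tangawizi Vodka", "industrial", 40.0),
    ("AWE", "Awere", "artisanal", 40.0),
    ("BOL", "Bolo", "artisanal", 40.0),
    ("TEB", "Teso Bar", "artisanal", 40.0),
    ("NSB", "Nsambya", "artisanal", 40.0),
    ("TGL", "The Glenlivet", "reference", 40.0),
]

# Published per-metal summary statistics (μg/L):
# Sum, mean, SD, minimum, Q1, median, Q3, maximum, IQR over the 18 brands.
_SUMMARY_ROWS = [
    ("Cu", 19414, 1079, 2939, 0.8, 1.5, 3.4, 313.0, 12100, 311.5),
    ("Al", 768.9, 42.7, 39.8, 2.6, 16.7, 32.1, 57.9, 157.9, 41.2),
    ("Sr", 722.5, 40.1, 34.9, 0.3, 4.3, 56.4, 65.9, 98.5, 61.6),
    ("Zn", 537.4, 29.9, 80.8, 1.3, 3.9, 7.1, 17.9, 350.4, 14.0),
    ("Ba", 237.6, 13.2, 14.3, 0.2, 1.7, 10.8, 18.8, 49.4, 17.1),
    ("Mn", 229.0, 12.7, 13.0, 1.1, 3.9, 9.1, 15.4, 48.8, 11.5),
    ("Se", 52.2, 2.9, 8.3, 0.1, 0.2, 0.8, 1.9, 35.8, 1.7),
    ("As", 22.5, 1.3, 2.2, 0.2, 0.5, 0.6, 1.1, 9.7, 0.6),
    ("Ni", 20.4, 1.1, 1.2, 0.2, 0.6, 0.7, 1.5, 5.4, 0.9),
    ("V", 28.7, 1.0, 6.7, 0.0, 0.0, 0.0, 0.0, 27.6, 0.0),
    ("Cr", 16.2, 0.9, 1.7, 0.1, 0.2, 0.3, 0.4, 6.4, 0.3),
    ("Sn", 15.9, 0.9, 0.9, 0.1, 0.4, 0.5, 1.0, 3.2, 0.7),
    ("Sb", 12.9, 0.7, 0.4, 0.3, 0.5, 0.6, 0.9, 1.6, 0.4),
    ("Pb", 4.1, 0.2, 0.3, 0.1, 0.1, 0.1, 0.2, 1.1, 0.1),
    ("Co", 2.8, 0.1, 0.4, 0.0, 0.0, 0.0, 0.1, 1.8, 0.1),
    ("Mo", 2.1, 0.1, 0.1, 0.0, 0.1, 0.1, 0.1, 0.3, 0.1),
    ("Be", 0.63, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.0),
    ("Cd", 0.62, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.0),
    ("Ag", 0.07, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.0),
    ("Tl", 0.09, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.0),
]

# Published per-brand metal totals (μg/L), hazard indices over the metals,
# and "1 in x" ratio strings, ranked by HI.
_BRAND_RISK_ROWS = [
    ("TEB", 12143.0, 7.3e-2, "1/14"),
    ("AWE", 4342.0, 2.6e-2, "1/38"),
    ("REX", 794.5, 1.3e-2, "1/83"),
    ("NSB", 1479.0, 1.1e-2, "1/91"),
    ("BOL", 1340.0, 9.6e-3, "1/104"),
    ("TGL", 538.0, 5.7e-3, "1/192"),
    ("B5V", 200.8, 1.9e-3, "1/529"),
    ("B7W", 64.8, 1.5e-3, "1/714"),
    ("BEG", 148.4, 1.3e-3, "1/769"),
    ("GOV", 123.3, 1.1e-3, "1/909"),
    ("KPW", 166.5, 1.1e-3, "1/1000"),
    ("BRG", 123.3, 8.9e-4, "1/1136"),
    ("CW1", 43.3, 8.7e-4, "1/1176"),
    ("ROV", 164.1, 8.3e-4, "1/1266"),
    ("CW2", 113.6, 7.8e-4, "1/1300"),
    ("SAG", 138.9, 6.9e-4, "1/1493"),
    ("UGW", 16.1, 6.3e-4, "1/1639"),
    ("V6T", 148.5, 5.8e-4, "1/1818"),
]

# Copper levels (μg/L) in the copper-dominated brands, with Cu's share of
# each brand's metal total.
_CU_FOOTNOTE = {
    "AWE": (4214.0, 97), "BOL": (1230.0, 92), "NSB": (1397.0, 94),
    "TEB": (12100.0, 100), "TGL": (407.0, 76),
}


@dataclass
class StudyFixture:
    """The study's printed tables as in-memory objects."""

    brands: pd.DataFrame          # id, name, class, abv
    profile: ExposureProfile
    reference: ToxicityReference
    summary_stats: pd.DataFrame   # per-metal Sum..IQR
    brand_risk: pd.DataFrame      # per-brand metal total, HI (metals), ratio
    cu_levels: pd.Series          # Cu μg/L in the Cu-dominated brands
    cu_share_pct: pd.Series       # Cu share of those brands' totals, %
    ethanol_hi: dict[float, float]  # abv %v/v → HI
    cancer_risk: float            # pooled lifetime risk over As, Cr, Pb

    @property
    def n_brands(self) -> int:
        return len(self.brands)


def study_fixture() -> StudyFixture:
    """The in-print study data: 18 brands, exposure profile, per-metal
    summary statistics, per-brand hazard indices and the copper footnotes."""
    brands = pd.DataFrame(_BRAND_ROWS,
                          columns=["id", "name", "class", "abv"]).set_index("id")
    summary = pd.DataFrame(
        _SUMMARY_ROWS,
        columns=["analyte", "Sum", "mean", "SD", "minimum", "Q1", "Median",
                 "Q3", "maximum", "IQR"]).set_index("analyte")
    brand_risk = pd.DataFrame(
        _BRAND_RISK_ROWS,
        columns=["brand", "metal_total", "HI_metals", "ratio"]).set_index("brand")
    cu = pd.Series({k: v[0] for k, v in _CU_FOOTNOTE.items()}, name="Cu")
    cu_share = pd.Series({k: v[1] for k, v in _CU_FOOTNOTE.items()},
                         name="cu_share_pct", dtype=float)
    return StudyFixture(
        brands=brands,
        profile=ExposureProfile(),
        reference=builtin_reference(),
        summary_stats=summary,
        brand_risk=brand_risk,
        cu_levels=cu,
        cu_share_pct=cu_share,
        ethanol_hi={40.0: 4.1, 20.0: 1.0},
        cancer_risk=9.8e-6,
    )
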