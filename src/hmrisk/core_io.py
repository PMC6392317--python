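"""Data model and file I/O for concentration panels, toxicity references and
exposure profiles.

Concentration panels are brands × analytes tables of measured levels:
micrograms per litre for metals, percent (v/v) for ethanol.  Values below the
per-analyte method detection limit (MDL) are *censored* — the instrument
cannot distinguish them from blank — and carry a flag so downstream statistics
can substitute them under an explicit, recorded policy rather than silently.

All tabular I/O is delimited text (UTF-8, "." decimal, first column the brand
id); exposure profiles are YAML/JSON mappings with keys IR, EF, ED, BW, ATn,
CF, Mc_convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "METALS",
    "ETHANOL",
    "KNOWN_ANALYTES",
    "ConcentrationPanel",
    "ExposureProfile",
    "ToxicityReference",
    "QCRecord",
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "apply_nondetect_policy",
    "read_mdl_table",
    "read_profile",
    "write_profile",
    "read_reference",
    "write_reference",
    "builtin_reference",
    "validate_qc",
    "exposure_duration_years",
    "exposure_duration_days",
    "averaging_time_days",
]

#: The 20 trace metals quantified in the beverage panel, plus ethanol.
METALS: tuple[str, ...] = (
    "Ag", "Al", "As", "Ba", "Be", "Cd", "Co", "Cr", "Cu", "Mn",
    "Mo", "Ni", "Pb", "Sb", "Se", "Sn", "Sr", "Tl", "V", "Zn",
)
ETHANOL = "ethanol"
KNOWN_ANALYTES: tuple[str, ...] = METALS + (ETHANOL,)

ND_TOKEN = "ND"

NondetectPolicy = Literal["zero", "half_mdl", "mdl"]


class PanelFormatError(ValueError):
    """Raised when a concentration-panel file violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationPanel:
    """Brands × analytes concentration matrix with censoring metadata.

    Attributes
    ----------
    levels : pandas.DataFrame
        Measured levels, rows = brands, columns = analytes.  μg/L for metals,
        % v/v for ethanol.  Censored cells hold the value assigned by the
        current non-detect policy.
    sds : pandas.DataFrame or None
        Duplicate-measurement standard deviations, same shape and units.
    censored : pandas.DataFrame
        Boolean mask, True where the measurement fell below the MDL.
    mdl : pandas.Series
        Per-analyte method detection limit, μg/L (NaN where not stated).
    units : dict
        Analyte → unit string ("ug/L" or "% v/v").
    provenance : list of str
        Audit trail of policies applied (read, substitution, ...).
    density_kg_per_L : float
        Drink density used to convert μg/L to μg/kg; 1.0 treats the two as
        interchangeable, which reproduces the conventional arithmetic for
        aqueous spirits.
    """

    levels: pd.DataFrame
    censored: pd.DataFrame
    mdl: pd.Series
    sds: pd.DataFrame | None = None
    units: dict[str, str] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    density_kg_per_L: float = 1.0

    def __post_init__(self) -> None:
        if not self.units:
            self.units = {
                a: ("% v/v" if a == ETHANOL else "ug/L")
                for a in self.levels.columns
            }
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        lv = self.levels
        if lv.index.duplicated().any():
            dups = lv.index[lv.index.duplicated()].unique().tolist()
            raise PanelFormatError(f"duplicate brand id: {dups}")
        if lv.columns.duplicated().any():
            dups = lv.columns[lv.columns.duplicated()].unique().tolist()
            raise PanelFormatError(f"duplicate analyte id: {dups}")
        if self.censored.shape != lv.shape:
            raise PanelFormatError("censored mask shape differs from levels")
        if self.sds is not None and self.sds.shape != lv.shape:
            raise PanelFormatError("sds shape differs from levels")
        vals = lv.to_numpy(dtype=float)
        cens = self.censored.to_numpy(dtype=bool)
        if np.any(vals[~cens] < 0):
            raise PanelFormatError("negative level in uncensored cell")

    @property
    def brand_ids(self) -> list[str]:
        return list(self.levels.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def n_brands(self) -> int:
        return len(self.levels.index)

    def metals(self) -> list[str]:
        return [a for a in self.analyte_ids if a != ETHANOL]

    def copy(self) -> "ConcentrationPanel":
        return ConcentrationPanel(
            levels=self.levels.copy(),
            censored=self.censored.copy(),
            mdl=self.mdl.copy(),
            sds=None if self.sds is None else self.sds.copy(),
            units=dict(self.units),
            provenance=list(self.provenance),
            density_kg_per_L=self.density_kg_per_L,
        )


@dataclass(frozen=True)
class ExposureProfile:
    """Exposure parameters of the average-daily-intake model.

    The intake equation is evaluated as

        ADI = Mc × IR × 10⁻³ × EF × ED / (BW × ATn)

    with Mc in mg contaminant per kg of drink, IR the ingestion rate in g of
    drink-equivalent per day, EF the exposure frequency in days/year, ED the
    exposure duration in years, BW the body weight in kg and ATn the
    averaging time in days.  ED is kept in years and ATn in days because the
    published parameterisation uses exactly these units; the 10⁻³ absorbs the
    g→kg conversion of IR.
    """

    IR: float = 78.54      # g/day
    EF: float = 240.0      # day/year
    ED: float = 43.65      # year
    BW: float = 60.0       # kg
    ATn: float = 21407.0   # day
    CF: float = 1e-3       # conversion factor in the intake equation
    Mc_convention: str = "mass_fraction"  # ethanol Mc rule, see exposure_risk

    def __post_init__(self) -> None:
        for name in ("IR", "EF", "ED", "BW", "ATn", "CF"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.EF > 365:
            raise ValueError("EF cannot exceed 365 day/year")
        if self.ED * 365 > self.ATn * (1 + 1e-9):
            raise ValueError("exposure duration exceeds the averaging lifespan")

    def to_dict(self) -> dict:
        return {
            "IR": self.IR, "EF": self.EF, "ED": self.ED, "BW": self.BW,
            "ATn": self.ATn, "CF": self.CF, "Mc_convention": self.Mc_convention,
        }


@dataclass
class ToxicityReference:
    """Per-analyte oral reference doses and cancer slope factors.

    ``table`` has index = analyte and columns ``rfd`` (mg/kg·day, NaN where no
    oral RfD is established), ``csf`` ((mg/kg·day)⁻¹, NaN where none) and
    ``source`` (free-text provenance).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"rfd", "csf", "source"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"toxicity reference missing columns: {sorted(missing)}")
        rfd = self.table["rfd"]
        if (rfd.dropna() <= 0).any():
            raise ValueError("RfD must be > 0 where present")
        csf = self.table["csf"]
        if (csf.dropna() < 0).any():
            raise ValueError("CSF must be >= 0 where present")

    def rfd(self, analyte: str) -> float | None:
        v = self.table.at[analyte, "rfd"] if analyte in self.table.index else np.nan
        return None if pd.isna(v) else float(v)

    def csf(self, analyte: str) -> float | None:
        v = self.table.at[analyte, "csf"] if analyte in self.table.index else np.nan
        return None if pd.isna(v) else float(v)

    def analytes_with_csf(self) -> list[str]:
        return list(self.table.index[self.table["csf"].notna()])


@dataclass
class QCRecord:
    """One quality-control measurement batch entry.

    kind ``blank`` passes iff every analyte level is below its MDL;
    ``spike_duplicate`` passes iff recovery (measured/expected) lies inside
    the configured band for every spiked analyte; ``vessel_leach`` follows the
    blank rule (a storage vessel must not contribute detectable metal).
    """

    kind: Literal["blank", "spike_duplicate", "vessel_leach"]
    levels: Mapping[str, float]
    expected: Mapping[str, float] | None = None
    label: str = ""


# ---------------------------------------------------------------------------
# exposure-duration helpers (lifetime bookkeeping)
# ---------------------------------------------------------------------------

def exposure_duration_years(lifespan_years: float = 58.65,
                            start_age_years: float = 15.0) -> float:
    """Years of exposure: life expectancy minus the age drinking begins."""
    if start_age_years >= lifespan_years:
        raise ValueError("start age must precede life expectancy")
    return lifespan_years - start_age_years


def exposure_duration_days(lifespan_years: float = 58.65,
                           start_age_years: float = 15.0) -> float:
    """365 × (lifespan − start age), in days."""
    return 365.0 * exposure_duration_years(lifespan_years, start_age_years)


def averaging_time_days(lifespan_years: float = 58.65) -> float:
    """Averaging time ATn: the full lifespan expressed in days."""
    if lifespan_years <= 0:
        raise ValueError("lifespan must be positive")
    return 365.0 * lifespan_years


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if "\t" in head else ","


def read_mdl_table(source: str | Path | Mapping[str, float] | pd.Series) -> pd.Series:
    """Read per-analyte method detection limits from a mapping or a 2-column
    delimited file (analyte, mdl)."""
    if isinstance(source, pd.Series):
        return source.astype(float)
    if isinstance(source, Mapping):
        return pd.Series(source, dtype=float)
    path = Path(source)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    return df.iloc[:, 0].astype(float)


def read_panel(
    table_path: str | Path,
    mdl_table: str | Path | Mapping[str, float] | pd.Series | None = None,
    *,
    nondetect_policy: NondetectPolicy = "zero",
    allow_unknown_analytes: bool = False,
) -> ConcentrationPanel:
    """Read a brands × analytes panel from delimited text.

    The header row names analytes; the first column holds brand ids; cells are
    numeric or the non-detect token ``ND``.  Columns named ``<analyte>_sd``
    are read as duplicate-measurement standard deviations.  Cells that are
    ``ND`` or fall below the analyte's MDL are flagged censored, and the
    configured substitution policy is applied to them immediately so the
    returned levels are always numeric.
    """
    path = Path(table_path)
    raw = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise PanelFormatError(f"duplicate brand id: {dups}")

    sd_cols = [c for c in raw.columns if c.endswith("_sd")]
    level_cols = [c for c in raw.columns if not c.endswith("_sd")]
    if not allow_unknown_analytes:
        unknown = [c for c in level_cols if c not in KNOWN_ANALYTES]
        if unknown:
            raise PanelFormatError(f"unknown analyte symbol: {unknown}")

    mdl = read_mdl_table(mdl_table) if mdl_table is not None else pd.Series(dtype=float)
    mdl = mdl.reindex(level_cols)

    def _parse(cell: str) -> tuple[float, bool]:
        cell = cell.strip()
        if cell.upper() == ND_TOKEN or cell == "":
            return np.nan, True
        v = float(cell)
        if v < 0:
            raise PanelFormatError(f"negative level: {v!r}")
        return v, False

    n, m = raw.shape[0], len(level_cols)
    levels = np.empty((n, m))
    cens = np.zeros((n, m), dtype=bool)
    for j, col in enumerate(level_cols):
        for i, cell in enumerate(raw[col]):
            levels[i, j], cens[i, j] = _parse(cell)
        lim = mdl.get(col, np.nan)
        if not np.isnan(lim):
            below = (~cens[:, j]) & (levels[:, j] < lim)
            cens[:, j] |= below

    levels_df = pd.DataFrame(levels, index=raw.index, columns=level_cols)
    cens_df = pd.DataFrame(cens, index=raw.index, columns=level_cols)
    sds_df = None
    if sd_cols:
        sds_df = pd.DataFrame(
            {c[:-3]: pd.to_numeric(raw[c]) for c in sd_cols}, index=raw.index
        ).reindex(columns=level_cols)

    panel = ConcentrationPanel(
        levels=levels_df, censored=cens_df, mdl=mdl, sds=sds_df,
        provenance=[f"read:{path.name}"],
    )
    return apply_nondetect_policy(panel, nondetect_policy)


def write_panel(panel: ConcentrationPanel, path: str | Path, *, sep: str = ",") -> Path:
    """Write a panel back to delimited text, restoring ``ND`` for censored
    cells so that read → write round-trips every numeric cell and flag."""
    path = Path(path)
    out = panel.levels.astype(object).copy()
    out[panel.censored] = ND_TOKEN
    if panel.sds is not None:
        for a in panel.analyte_ids:
            col = panel.sds[a]
            if col.notna().any():
                out[f"{a}_sd"] = col
    out.index.name = "brand"
    out.to_csv(path, sep=sep)
    return path


def apply_nondetect_policy(panel: ConcentrationPanel,
                           policy: NondetectPolicy) -> ConcentrationPanel:
    """Substitute censored cells by 0, MDL/2 or MDL.

    Idempotent for a fixed policy; uncensored cells are never touched.  The
    three policies bracket the unknown true value of a non-detect, and the
    choice is recorded in the panel's provenance so every downstream table can
    state which bound it reflects.
    """
    if policy not in ("zero", "half_mdl", "mdl"):
        raise ValueError(f"unknown non-detect policy: {policy!r}")
    out = panel.copy()
    cens = out.censored.to_numpy(dtype=bool)
    if cens.any():
        mdl = out.mdl.reindex(out.analyte_ids).to_numpy(dtype=float)
        need = cens.any(axis=0) & np.isnan(mdl)
        if need.any():
            bad = [a for a, b in zip(out.analyte_ids, need) if b]
            raise ValueError(f"censored cells but no MDL for: {bad}")
        factor = {"zero": 0.0, "half_mdl": 0.5, "mdl": 1.0}[policy]
        sub = np.broadcast_to(mdl * factor, out.levels.shape)
        vals = out.levels.to_numpy(dtype=float)
        vals[cens] = sub[cens]
        out.levels = pd.DataFrame(vals, index=out.levels.index,
                                  columns=out.levels.columns)
    out.provenance.append(f"nondetect:{policy}")
    return out


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

_PROFILE_KEYS = ("IR", "EF", "ED", "BW", "ATn", "CF", "Mc_convention")


def read_profile(path: str | Path) -> ExposureProfile:
    """Read an exposure profile from YAML or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    unknown = set(data) - set(_PROFILE_KEYS)
    if unknown:
        raise ValueError(f"unknown exposure-profile keys: {sorted(unknown)}")
    return ExposureProfile(**data)


def write_profile(profile: ExposureProfile, path: str | Path) -> Path:
    path = Path(path)
    data = profile.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# toxicity reference
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> ToxicityReference:
    """Read an RfD/CSF table from delimited text (analyte, rfd, csf, source)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.columns = [c.lower() for c in df.columns]
    if "source" not in df.columns:
        df["source"] = "user table"
    return ToxicityReference(df[["rfd", "csf", "source"]])


def write_reference(ref: ToxicityReference, path: str | Path, *, sep: str = ",") -> Path:
    path = Path(path)
    out = ref.table.copy()
    out.index.name = "analyte"
    out.to_csv(path, sep=sep)
    return path


# Oral RfDs (mg/kg·day): ethanol and Pb follow this study's stated
# conventions; the metals use public US EPA oral values (IRIS unless noted).
# CSFs ((mg/kg·day)^-1) exist for As, Cr(VI) and Pb only.
_BUILTIN_ROWS = [
    # analyte, rfd,      csf,    source
    ("Ag",     5e-3,     None,   "US EPA IRIS, silver, oral RfD"),
    ("Al",     1.0,      None,   "US EPA PPRTV, aluminum, oral RfD"),
    ("As",     3e-4,     1.5,    "US EPA IRIS, inorganic arsenic, oral RfD + oral slope factor"),
    ("Ba",     0.2,      None,   "US EPA IRIS, barium, oral RfD"),
    ("Be",     2e-3,     None,   "US EPA IRIS, beryllium, oral RfD"),
    ("Cd",     5e-4,     None,   "US EPA IRIS, cadmium (water), oral RfD"),
    ("Co",     3e-4,     None,   "US EPA PPRTV, cobalt, oral RfD"),
    ("Cr",     3e-3,     0.5,    "US EPA IRIS, chromium(VI), oral RfD; slope factor: study convention"),
    ("Cu",     4e-2,     None,   "US EPA HEAST, copper, oral RfD"),
    ("Mn",     0.14,     None,   "US EPA IRIS, manganese (diet), oral RfD"),
    ("Mo",     5e-3,     None,   "US EPA IRIS, molybdenum, oral RfD"),
    ("Ni",     2e-2,     None,   "US EPA IRIS, nickel soluble salts, oral RfD"),
    ("Pb",     1.5,      8.5e-3, "study convention (no established oral RfD for lead); slope factor: CalEPA"),
    ("Sb",     4e-4,     None,   "US EPA IRIS, antimony, oral RfD"),
    ("Se",     5e-3,     None,   "US EPA IRIS, selenium, oral RfD"),
    ("Sn",     0.6,      None,   "US EPA HEAST, tin, oral RfD"),
    ("Sr",     0.6,      None,   "US EPA IRIS, strontium, oral RfD"),
    ("Tl",     1e-5,     None,   "US EPA PPRTV, thallium soluble salts, oral RfD"),
    ("V",      5e-3,     None,   "US EPA, vanadium, oral RfD"),
    ("Zn",     0.3,      None,   "US EPA IRIS, zinc, oral RfD"),
    (ETHANOL,  62.0,     None,   "study convention (US EPA 2016 oral benchmark for ethanol)"),
]


def builtin_reference() -> ToxicityReference:
    """The RfD/CSF table shipped with the package (user-overridable)."""
    df = pd.DataFrame(_BUILTIN_ROWS, columns=["analyte", "rfd", "csf", "source"])
    df = df.set_index("analyte")
    df["rfd"] = df["rfd"].astype(float)
    df["csf"] = df["csf"].astype(float)
    return ToxicityReference(df)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def validate_qc(
    records: Sequence[QCRecord],
    mdl: pd.Series | Mapping[str, float],
    recovery_band: tuple[float, float] = (0.75, 1.25),
) -> dict:
    """Assess a QC batch: blanks/vessel leaches must be non-detect for every
    analyte, spike duplicates must recover within ``recovery_band`` of the
    expected level.  The batch is usable only if every record passes and at
    least one blank is present."""
    if not records:
        raise ValueError("no QC in batch")
    mdl = pd.Series(mdl, dtype=float)
    lo, hi = recovery_band
    results = []
    for rec in records:
        if rec.kind in ("blank", "vessel_leach"):
            fails = {
                a: lvl for a, lvl in rec.levels.items()
                if not np.isnan(mdl.get(a, np.nan)) and lvl >= mdl[a]
            }
            passed = not fails
            detail = {"detected_above_mdl": fails}
        elif rec.kind == "spike_duplicate":
            if rec.expected is None:
                raise ValueError("spike_duplicate record lacks expected levels")
            recov = {a: rec.levels.get(a, 0.0) / exp
                     for a, exp in rec.expected.items() if exp > 0}
            fails = {a: r for a, r in recov.items() if not (lo <= r <= hi)}
            passed = not fails
            detail = {"recovery": recov, "out_of_band": fails}
        else:
            raise ValueError(f"unknown QC record kind: {rec.kind!r}")
        results.append({"kind": rec.kind, "label": rec.label,
                        "passed": passed, **detail})
    has_blank = any(r.kind == "blank" for r in records)
    usable = has_blank and all(r["passed"] for r in results)
    return {
        "usable": usable,
        "has_blank": has_blank,
        "recovery_band": [lo, hi],
        "records": results,
    }
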