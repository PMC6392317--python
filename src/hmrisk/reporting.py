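"""Pipeline orchestration, run manifests and plain-text report rendering.

``run_pipeline`` executes the four risk-assessment steps in sequence —
hazard identification (panel intake + QC-aware censoring policy), daily
intake estimation, risk estimation (THQ/CR) and risk characterization
(HI, categories, clustering) — and writes every table as delimited text
plus a JSON manifest sufficient to re-run the analysis bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import (
    cophenetic_correlation,
    cut_tree,
    merge_table,
    split_half_stability,
    squared_euclidean,
    to_newick,
    ward_agglomerate,
)
from .core_io import (
    ETHANOL,
    ConcentrationPanel,
    ExposureProfile,
    ToxicityReference,
)
from .descriptive import composition_shares, summarize_panel
from .exposure_risk import RiskTable, compute_risk_table

log = logging.getLogger("hmrisk")

__all__ = ["PipelineConfig", "run_pipeline", "render_tables", "file_sha256"]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Everything that determines a pipeline run besides the input tables."""

    mode: str = "published"                  # ethanol ADI pathway
    nondetect: str = "zero"              # censored-cell substitution
    row_percent_axis: str = "rows"       # orientation of the % transform
    cluster: bool = True
    cluster_exclude: tuple[str, ...] = ("Cu", ETHANOL)
    cut_height: float | None = None
    n_splits: int = 0                    # split-half stability replicates
    seed: int = 0
    quartile_method: str = "inclusive"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["cluster_exclude"] = list(self.cluster_exclude)
        return d


def run_pipeline(
    panel: ConcentrationPanel,
    profile: ExposureProfile,
    reference: ToxicityReference,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    input_paths: dict[str, str] | None = None,
) -> dict:
    """Run the full analysis and write its outputs under ``out_dir``.

    Returns a dict with the in-memory results (risk table, summaries,
    clustering) and the manifest.  On any stage failure the partially
    written output directory is cleared before the exception propagates.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "hazard identification"
        if panel.n_brands == 0:
            raise ValueError("no brands in panel")
        log.info("%s: %d brands x %d analytes", stage, panel.n_brands,
                 len(panel.analyte_ids))

        stage = "descriptive analysis"
        summary = summarize_panel(panel, quartile_method=cfg.quartile_method)
        shares = composition_shares(panel)
        log.info("%s: %d analytes summarized", stage, len(summary))

        stage = "daily intake and risk estimation"
        risk = compute_risk_table(panel, profile, reference, mode=cfg.mode,
                                  row_percent_axis=cfg.row_percent_axis)
        log.info("%s: THQ %d x %d", stage, *risk.thq.shape)

        stage = "risk characterization"
        cluster_out = None
        if cfg.cluster and panel.n_brands >= 2:
            feats = risk.thq_rowpct.drop(
                columns=[c for c in cfg.cluster_exclude if c in risk.thq_rowpct],
                errors="ignore").dropna(axis=0, how="any")
            if len(feats) >= 2 and feats.shape[1] >= 1:
                D = squared_euclidean(feats)
                tree = ward_agglomerate(D)
                coph = cophenetic_correlation(D, tree)
                cluster_out = {"tree": tree, "distance": D,
                               "cophenetic_correlation": coph}
                if cfg.cut_height is not None:
                    cluster_out["cut"] = cut_tree(tree, cfg.cut_height)
                if cfg.n_splits > 0 and len(feats) >= 4:
                    cluster_out["stability"] = split_half_stability(
                        feats, cfg.n_splits, cfg.seed)
                log.info("%s: clustered %d items, cophenetic r=%s",
                         stage, len(feats), coph)

        stage = "writing outputs"
        def _w(df: pd.DataFrame, name: str) -> None:
            p = out / name
            df.to_csv(p)
            written.append(p)

        _w(summary, "summary.csv")
        _w(risk.adi, "adi.csv")
        _w(risk.thq, "thq.csv")
        _w(risk.thq_rowpct, "thq_rowpct.csv")
        hi = risk.hi.copy()
        hi.insert(0, "metal_content", panel.levels[panel.metals()].sum(axis=1))
        _w(hi.sort_values("HI", ascending=False), "hi.csv")
        _w(risk.hi_with_ethanol, "hi_with_ethanol.csv")
        cancer = risk.cancer.copy()
        _w(cancer, "cancer_risk.csv")
        if cluster_out is not None:
            _w(merge_table(cluster_out["tree"]), "cluster_merges.csv")
            p = out / "dendrogram.nwk"
            p.write_text(to_newick(cluster_out["tree"]) + "\n", encoding="utf-8")
            written.append(p)
            if "stability" in cluster_out:
                p = out / "stability.json"
                p.write_text(json.dumps(cluster_out["stability"], indent=2),
                             encoding="utf-8")
                written.append(p)

        manifest = {
            "package": "hmrisk",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "inputs": {
                k: {"path": v, "sha256": file_sha256(v) if Path(v).exists() else None}
                for k, v in (input_paths or {}).items()
            },
            "config": cfg.to_dict(),
            "profile": profile.to_dict(),
            "panel_provenance": panel.provenance,
            "pooled_cancer_risk": risk.cancer_pooled["CR"],
            "outputs": {p.name: file_sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                           encoding="utf-8")
        return {"risk": risk, "summary": summary, "shares": shares,
                "cluster": cluster_out, "manifest": manifest, "out_dir": out}
    except Exception:
        log.error("pipeline failed at stage: %s", stage)
        for p in written:
            p.unlink(missing_ok=True)
        raise


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _sig3(x: float) -> str:
    if x == 0:
        return "0"
    return f"{x:.3g}"


def render_tables(results: dict) -> str:
    """Render a plain-text report: a per-metal summary section (Sum..IQR), a
    per-brand hazard section ranked by HI descending, and the clustering
    section when available."""
    risk: RiskTable = results["risk"]
    summary: pd.DataFrame = results["summary"]
    lines: list[str] = []

    lines.append("Per-metal summary statistics (ug/L)")
    cols = ["Sum", "mean", "SD", "minimum", "Q1", "Median", "Q3", "maximum", "IQR"]
    header = f"{'':8s}" + "".join(f"{c:>10s}" for c in cols)
    lines.append(header)
    for a, row in summary.iterrows():
        lines.append(f"{a:8s}" + "".join(f"{_sig3(row[c]):>10s}" for c in cols))
    lines.append("")

    lines.append("Per-brand hazard indices (metals), ranked")
    lines.append(f"{'brand':8s}{'metal content':>15s}{'HI':>12s}{'ratio':>10s}{'category':>10s}")
    hi = risk.brands_by_hi()
    totals = results.get("metal_totals")
    for b, row in hi.iterrows():
        tot = "" if totals is None else _sig3(totals.get(b, float("nan")))
        lines.append(f"{b:8s}{tot:>15s}{row['HI']:>12.2e}{row['ratio']:>10s}"
                     f"{row['category']:>10s}")
    lines.append("")

    lines.append("Per-brand lifetime carcinogenic risk (analytes with CSF)")
    lines.append(f"{'brand':8s}{'CR':>12s}{'1 case per':>14s}")
    for b, row in risk.cancer.iterrows():
        ppc = row["persons_per_case"]
        ppc_s = "inf" if ppc == float("inf") else f"{int(ppc):,d}"
        lines.append(f"{b:8s}{row['CR']:>12.2e}{ppc_s:>14s}")
    lines.append("")

    cl = results.get("cluster")
    if cl:
        lines.append("Cluster analysis of row-percent THQ profiles")
        r = cl.get("cophenetic_correlation")
        lines.append(f"cophenetic correlation: "
                     f"{'undefined' if r is None else f'{r:.4f}'}")
        if "cut" in cl:
            counts = cl["cut"].value_counts().sort_index()
            lines.append("clusters at cut: "
                         + ", ".join(f"{k}: n={v}" for k, v in counts.items()))
        if "stability" in cl:
            st = cl["stability"]
            lines.append(f"split-half stability: mean agreement "
                         f"{st['mean_agreement']:.3f} over {st['n_splits']} splits")
        lines.append("")
    return "\n".join(lines)
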