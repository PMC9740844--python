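"""End-to-end analysis: proteomics -> enrichment -> metabolomics.

The over- and underexpressed protein sets are enriched separately (they
answer different biological questions), and every output table is stamped
with the hash of the configuration that produced it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .enrichment import fisher_enrichment, filter_significant, read_gmt, results_to_frame
from .metabolomics import (
    MetabolitePanel,
    PLSDA,
    cluster_heatmap,
    univariate_panel,
    univariate_to_frame,
    volcano,
)
from .proteomics import classify_differential, run_proteomics

logger = logging.getLogger(__name__)

__all__ = ["run_all", "run_metabolomics"]


def _stamp(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_metabolomics(panel: MetabolitePanel, cfg: PipelineConfig, out: Path | None = None) -> dict:
    """Metabolomics stage: PLS-DA/VIP, univariate tests, volcano, clustering."""
    m = cfg.metabolomics
    results = PLSDA.from_panel(panel, n_components=m.n_components).fit()
    vip = results.vip.sort_values(ascending=False)
    discriminant = results.discriminant_features(m.vip_cutoff)
    uni = univariate_panel(panel, alpha_normality=m.alpha_normality, alpha=m.alpha)
    volc = volcano(uni, fc_threshold_log2=m.volcano_fc_threshold_log2, p_threshold=m.alpha)
    clust = cluster_heatmap(panel, top_k=m.heatmap_top_k, linkage=m.linkage, univariate=uni)
    summary = {
        "n_metabolites": len(panel.metabolite_ids),
        "explained_y_variance_pct": [round(100 * v, 2) for v in results.explained_y_variance],
        "discriminant_vip": {k: round(float(v), 3) for k, v in discriminant.items()},
        "n_increased": int((volc["volcano_class"] == "increased").sum()),
        "n_decreased": int((volc["volcano_class"] == "decreased").sum()),
    }
    if out is not None:
        cfg_hash = cfg.config_hash()
        _stamp(univariate_to_frame(uni).reset_index(), out / "metabolomics_univariate.tsv", cfg_hash)
        _stamp(vip.rename_axis("metabolite_id").reset_index(), out / "metabolomics_vip.tsv", cfg_hash)
        _stamp(volc.reset_index(), out / "metabolomics_volcano.tsv", cfg_hash)
        (out / "metabolomics_clustering.json").write_text(json.dumps(clust, indent=2) + "\n")
    return {"plsda": results, "vip": vip, "univariate": uni, "volcano": volc,
            "clustering": clust, "summary": summary}


def run_all(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the machine-readable summary.

    Writes <out_dir>/summary.json plus per-stage tables.  A stage whose
    inputs are not configured is skipped and marked so in the summary;
    a stage that is configured but whose input is missing aborts.
    """
    cfg.validate()
    out = Path(cfg.io.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    summary: dict = {"version": __version__, "seed": cfg.seed, "config_hash": cfg_hash,
                     "thresholds": cfg.to_dict()}

    over: list[str] = []
    under: list[str] = []
    universe: list[str] = []
    if cfg.io.rsc_table:
        # precomputed per-protein Rsc (e.g. a published table): classify only
        path = Path(cfg.io.rsc_table)
        if not path.exists():
            raise FileNotFoundError(f"proteomics stage: missing Rsc table {path}")
        table = pd.read_csv(path, sep="\t")
        classified, psum = classify_differential(
            zip(table["accession"], table["rsc"]), threshold=cfg.proteomics.rsc_threshold
        )
        over = [r.accession for r in classified if r.diff_class == "over"]
        under = [r.accession for r in classified if r.diff_class == "under"]
        universe = [r.accession for r in classified]
        out_tab = table.assign(diff_class=[r.diff_class for r in classified])
        _stamp(out_tab, out / "proteomics_results.tsv", cfg_hash)
        summary["proteomics"] = psum
    elif cfg.io.identifications:
        path = Path(cfg.io.identifications)
        if not path.exists():
            raise FileNotFoundError(f"proteomics stage: missing input {path}")
        p = cfg.proteomics
        try:
            res = run_proteomics(
                path, focus=p.group_a, reference=p.group_b, out_dir=out,
                f=p.f, rsc_threshold=p.rsc_threshold,
                min_peptides=p.min_peptides, min_score=p.min_score,
            )
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"proteomics stage failed: {exc}") from exc
        over, under = res.over, res.under
        universe = [e.accession for e in res.entries]
        summary["proteomics"] = res.summary
    else:
        summary["proteomics"] = "skipped (no identifications path)"

    if cfg.io.gmt:
        gmt_path = Path(cfg.io.gmt)
        if not gmt_path.exists():
            raise FileNotFoundError(f"enrichment stage: missing GMT {gmt_path}")
        if not universe:
            raise RuntimeError("enrichment stage requires the proteomics stage")
        e = cfg.enrichment
        sets = read_gmt(gmt_path)
        enrichment_summary = {}
        for name, query in (("over", over), ("under", under)):
            try:
                res_e = fisher_enrichment(
                    query, universe, sets,
                    min_background_members=e.min_background_members, ease=e.ease,
                )
            except Exception as exc:
                raise RuntimeError(f"enrichment stage ({name}) failed: {exc}") from exc
            sig = filter_significant(res_e, e.alpha_p, e.alpha_fdr, e.mode)
            _stamp(results_to_frame(res_e), out / f"enrichment_{name}.tsv", cfg_hash)
            enrichment_summary[name] = {
                "n_terms_tested": len(res_e),
                "n_significant": len(sig),
                "significant_terms": [r.term_id for r in sig],
            }
        summary["enrichment"] = enrichment_summary
    else:
        summary["enrichment"] = "skipped (no GMT path)"

    if cfg.io.metabolite_panel:
        panel_path = Path(cfg.io.metabolite_panel)
        groups_path = Path(cfg.io.metabolite_groups or "")
        if not panel_path.exists() or not groups_path.exists():
            raise FileNotFoundError(
                "metabolomics stage: missing panel or group map "
                f"({panel_path}, {groups_path})"
            )
        panel = MetabolitePanel.from_tsv(panel_path, groups_path)
        try:
            met = run_metabolomics(panel, cfg, out)
        except Exception as exc:
            raise RuntimeError(f"metabolomics stage failed: {exc}") from exc
        summary["metabolomics"] = met["summary"]
    else:
        summary["metabolomics"] = "skipped (no metabolite panel path)"

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
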