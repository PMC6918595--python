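"""End-to-end pipeline: ingest -> quantitation -> DEP calling -> enrichment ->
overlap (-> validation, when densitometry / fetal-count inputs are given),
with a JSON run manifest of parameters and per-stage counts.

Re-running with the same configuration and inputs reproduces every output
file byte for byte (the manifest carries no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .concordance import (
    fc_correlation,
    fetal_loss_rate,
    read_densitometry,
    read_fetal_counts,
    wb_anova,
    wb_relative_expression,
)
from .differential import call_deps, dep_ids, summarize_contrasts
from .enrichment import AnnotationMap, fisher_enrichment, top_terms
from .errors import ConfigError, DataError
from .ingest import DEFAULT_CHANNEL_MAP, PSMTable, assign_uniqueness, filter_psms, read_psm_table
from .overlap import classify_shared_deps, venn_counts_frame
from .quant import DEFAULT_CONTRASTS, ContrastSpec, quantify_contrast

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    psm_paths: Sequence[str | Path]
    out_dir: str | Path
    annotation_path: str | Path | None = None
    terms_path: str | Path | None = None
    densitometry_path: str | Path | None = None
    fetal_counts_path: str | Path | None = None
    channel_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    contrasts: Sequence[ContrastSpec] = DEFAULT_CONTRASTS
    min_ion_score: float = 20.0
    max_fdr: float = 0.01
    up: float = 1.3
    down: float = 0.70
    alpha: float = 0.05
    top_bp: int = 15
    top_pathway: int = 5
    median_center: bool = False

    def __post_init__(self) -> None:
        if not self.psm_paths:
            raise ConfigError("at least one PSM table is required")
        if (self.annotation_path is None) != (self.terms_path is None):
            raise ConfigError("annotation and term-metadata paths must be given together")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def quantify_and_call(
    tables: list[PSMTable],
    contrasts: Sequence[ContrastSpec] = DEFAULT_CONTRASTS,
    up: float = 1.3,
    down: float = 0.70,
    alpha: float = 0.05,
    median_center: bool = False,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """In-memory quantitation + DEP calling for a set of contrasts.

    Returns ``(quant_by_contrast, calls_by_contrast)`` keyed by contrast name.
    """
    quant_by, calls_by = {}, {}
    for contrast in contrasts:
        quant = quantify_contrast(tables, contrast, median_center=median_center)
        quant_by[contrast.name] = quant
        calls_by[contrast.name] = call_deps(quant, up=up, down=down, alpha=alpha)
    return quant_by, calls_by


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write the result bundle to ``cfg.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "plexquant", "version": __version__},
        "parameters": {
            "min_ion_score": cfg.min_ion_score,
            "max_fdr": cfg.max_fdr,
            "up": cfg.up,
            "down": cfg.down,
            "alpha": cfg.alpha,
            "top_bp": cfg.top_bp,
            "top_pathway": cfg.top_pathway,
            "median_center": cfg.median_center,
            "channel_map": dict(cfg.channel_map),
            "contrasts": [
                {"name": c.name, "case": c.case_group, "control": c.control_group}
                for c in cfg.contrasts
            ],
        },
        # File names only (not absolute paths): identical inputs in different
        # directories must reproduce the bundle byte for byte.
        "inputs": {
            "psm_files": [Path(p).name for p in cfg.psm_paths],
            "annotation_file": Path(cfg.annotation_path).name if cfg.annotation_path else None,
            "densitometry_file": Path(cfg.densitometry_path).name if cfg.densitometry_path else None,
            "fetal_counts_file": Path(cfg.fetal_counts_path).name if cfg.fetal_counts_path else None,
        },
        "stages": {},
    }

    # --- ingest ---
    try:
        tables = [
            read_psm_table(p, channel_map=cfg.channel_map, pool_id=f"pool{i}")
            for i, p in enumerate(cfg.psm_paths, start=1)
        ]
        manifest["stages"]["ingest"] = {t.pool_id: len(t) for t in tables}
        tables = [filter_psms(t, cfg.min_ion_score, cfg.max_fdr) for t in tables]
        manifest["stages"]["filter"] = {t.pool_id: len(t) for t in tables}
        tables = assign_uniqueness(tables)
        manifest["stages"]["unique_psms"] = {
            t.pool_id: int(t.df["is_unique"].sum()) for t in tables
        }
    except (ConfigError, DataError) as exc:
        raise type(exc)(f"ingest stage failed: {exc}") from exc

    annotation = None
    if cfg.annotation_path is not None:
        annotation = AnnotationMap.from_tsv(cfg.annotation_path, cfg.terms_path)

    # --- quantitation / differential / enrichment per contrast ---
    quant_by, calls_by = {}, {}
    manifest["stages"]["contrasts"] = {}
    for contrast in cfg.contrasts:
        quant = quantify_contrast(tables, contrast, median_center=cfg.median_center)
        quant_by[contrast.name] = quant
        _write(
            quant.assign(quantified_in_all_pools=quant["quantified_in_all_pools"].astype(int)),
            out / f"quant_{contrast.name}.tsv",
        )
        calls = call_deps(quant, up=cfg.up, down=cfg.down, alpha=cfg.alpha)
        calls_by[contrast.name] = calls
        _write(
            calls.loc[calls["eligible"], ["protein_id", "fc_geomean", "p_value", "dep_class"]],
            out / f"deps_{contrast.name}.tsv",
        )
        _write(
            calls.loc[~calls["eligible"], ["protein_id", "fc_geomean", "p_value"]],
            out / f"ineligible_{contrast.name}.tsv",
        )
        entry = {
            "n_quantified": int(quant["quantified_in_all_pools"].sum()),
            "n_ineligible": int((~calls["eligible"]).sum()),
            "n_increased": int((calls["dep_class"] == "increased").sum()),
            "n_decreased": int((calls["dep_class"] == "decreased").sum()),
        }
        if annotation is not None:
            background = set(
                quant.loc[quant["quantified_in_all_pools"], "protein_id"]
            )
            enr = fisher_enrichment(dep_ids(calls), background, annotation)
            _write(enr, out / f"enrichment_{contrast.name}.tsv")
            _write(top_terms(enr, "BP", cfg.top_bp), out / f"top_BP_{contrast.name}.tsv")
            _write(
                top_terms(enr, "PATHWAY", cfg.top_pathway),
                out / f"top_PATHWAY_{contrast.name}.tsv",
            )
            entry["n_terms_tested"] = len(enr)
        manifest["stages"]["contrasts"][contrast.name] = entry

    summary = summarize_contrasts(calls_by, order=[c.name for c in cfg.contrasts])
    _write(summary, out / "dep_summary.tsv")

    # --- overlap ---
    dep_sets = {name: dep_ids(calls) for name, calls in calls_by.items()}
    if 2 <= len(dep_sets) <= 4:
        _write(venn_counts_frame(dep_sets), out / "venn_regions.tsv")
    for name_a, name_b in combinations(calls_by, 2):
        report = classify_shared_deps(calls_by[name_a], calls_by[name_b], name_a, name_b)
        _write(report, out / f"overlap_{name_a}__{name_b}.tsv")

    # --- orthogonal validation ---
    if cfg.densitometry_path is not None:
        dens = read_densitometry(cfg.densitometry_path)
        values, wb_summary = wb_relative_expression(dens)
        _write(values, out / "wb_relative_expression.tsv")
        _write(wb_summary, out / "wb_group_summary.tsv")
        _write(wb_anova(values), out / "wb_anova.tsv")
        corr = _wb_itraq_correlation(wb_summary, quant_by, cfg.contrasts)
        if corr is not None:
            _write(corr["pairs"], out / "wb_itraq_fold_changes.tsv")
            manifest["stages"]["wb_itraq_correlation"] = {
                "pearson_r": corr["r"], "p_value": corr["p"], "n": corr["n"],
            }
    if cfg.fetal_counts_path is not None:
        counts = read_fetal_counts(cfg.fetal_counts_path)
        rows = []
        for early, late in (("MSD49", "MSD72"), ("DUD49", "DUD72")):
            if {early, late} <= set(counts["group"]):
                r = fetal_loss_rate(counts, early, late)
                rows.append({"early_group": early, "late_group": late, **r})
        if rows:
            _write(pd.DataFrame(rows), out / "fetal_loss.tsv")
            manifest["stages"]["fetal_loss"] = {
                f"{r['early_group']}_to_{r['late_group']}": round(r["loss_pct"], 2)
                for r in rows
            }

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _wb_itraq_correlation(wb_summary, quant_by, contrasts):
    """Match WB group-mean ratios to reporter-ion fold changes per
    (protein, contrast) and correlate; None when fewer than 3 pairs match."""
    pairs = []
    means = wb_summary.set_index(["protein", "group"])["mean"]
    for contrast in contrasts:
        quant = quant_by[contrast.name].set_index("protein_id")
        for protein in wb_summary["protein"].unique():
            try:
                wb_fc = means[(protein, contrast.case_group)] / means[(protein, contrast.control_group)]
            except KeyError:
                continue
            if protein in quant.index:
                itraq_fc = quant.loc[protein, "fc_geomean"]
                pairs.append(
                    {
                        "protein_id": protein,
                        "contrast": contrast.name,
                        "wb_fc": wb_fc,
                        "itraq_fc": itraq_fc,
                    }
                )
    df = pd.DataFrame(pairs, columns=["protein_id", "contrast", "wb_fc", "itraq_fc"])
    df = df.dropna()
    if len(df) < 3:
        logger.warning("fewer than 3 matched WB/reporter fold-change pairs; correlation skipped")
        return None
    r, p, n = fc_correlation(df["wb_fc"], df["itraq_fc"])
    return {"pairs": df, "r": r, "p": p, "n": n}
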