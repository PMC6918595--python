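"""Protein-level relative quantitation from unique-peptide reporter ratios.

For a contrast (case group vs control group), each unique-peptide PSM yields
one ratio of the two reporter intensities read from the *same* spectrum.  A
protein's fold change in one replicate pool is the median of its
unique-peptide ratios in that pool; the combined fold change across R pools is
the geometric mean (prod(FC_r))^(1/R), defined only for proteins quantified in
every pool.  Significance is a two-tailed one-sample t-test of the protein's
within-spectrum log2 ratios (pooled over replicate pools) against 0 — the
reporter channels being compared come from the same spectrum, so the ratios
are intrinsically paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .ingest import PSMTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastSpec:
    """A named comparison of two channel groups, e.g. MSD49 vs DUD49."""

    name: str
    case_group: str
    control_group: str

    def __post_init__(self) -> None:
        if self.case_group == self.control_group:
            raise ConfigError(f"contrast {self.name!r}: case equals control")


#: The four breed/stage contrasts of the study design, in reporting order.
DEFAULT_CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec("DUD72_vs_DUD49", "DUD72", "DUD49"),
    ContrastSpec("MSD72_vs_MSD49", "MSD72", "MSD49"),
    ContrastSpec("MSD49_vs_DUD49", "MSD49", "DUD49"),
    ContrastSpec("MSD72_vs_DUD72", "MSD72", "DUD72"),
)


def peptide_ratios(table: PSMTable, contrast: ContrastSpec) -> pd.DataFrame:
    """Per-record case/control reporter ratios for unique-peptide PSMs.

    Records whose needed channels are missing or non-positive are skipped for
    this contrast only (logged).  Returns columns ``protein_id``,
    ``peptide_sequence``, ``ratio``, ``pool_id``.
    """
    if "is_unique" not in table.df.columns:
        raise DataError(
            f"pool {table.pool_id}: uniqueness not assigned; run assign_uniqueness first"
        )
    case_col = table.intensity_column(contrast.case_group)
    ctrl_col = table.intensity_column(contrast.control_group)
    df = table.df
    usable = (
        df["is_unique"]
        & df[case_col].notna()
        & df[ctrl_col].notna()
        & (df[case_col] > 0)
        & (df[ctrl_col] > 0)
    )
    n_skipped = int((df["is_unique"] & ~usable).sum())
    if n_skipped:
        logger.info(
            "pool %s, %s: skipped %d unique-peptide record(s) with missing/non-positive channels",
            table.pool_id, contrast.name, n_skipped,
        )
    sub = df[usable]
    return pd.DataFrame(
        {
            "protein_id": sub["protein_ids"].str[0],
            "peptide_sequence": sub["peptide_sequence"],
            "ratio": sub[case_col] / sub[ctrl_col],
            "pool_id": table.pool_id,
        }
    ).reset_index(drop=True)


def protein_quantity(ratios: pd.DataFrame) -> pd.Series:
    """Per-protein fold change for one pool: median of unique-peptide ratios.

    Even counts use midpoint interpolation (the usual median convention).
    """
    return ratios.groupby("protein_id")["ratio"].median()


def combine_fold_changes(fc_per_pool) -> float:
    """Geometric mean across pools, as (prod FC_r)^(1/R); NaN if any pool is missing."""
    v = np.asarray(list(fc_per_pool), dtype=float)
    if v.size == 0 or np.isnan(v).any():
        return float("nan")
    return float(np.prod(v) ** (1.0 / v.size))


def protein_pvalue(log2_ratios) -> float:
    """Two-tailed one-sample t-test of the mean log2 ratio against 0.

    Degenerate rules: fewer than 2 measurements -> NaN (undefined); zero
    sample variance with zero mean -> p = 1; zero variance with non-zero mean
    -> p = 0 (logged).
    """
    x = np.asarray(list(log2_ratios), dtype=float)
    if x.size < 2:
        return float("nan")
    if np.ptp(x) == 0.0:
        if x[0] == 0.0:
            return 1.0
        logger.info("zero-variance log-ratios with non-zero mean: p = 0 by convention")
        return 0.0
    return float(stats.ttest_1samp(x, 0.0).pvalue)


def _median_center(table: PSMTable) -> PSMTable:
    """Divide each reporter channel by its per-pool median over positive values."""
    from dataclasses import replace

    df = table.df.copy()
    for col in table.intensity_columns:
        pos = df[col][df[col] > 0]
        if len(pos):
            df[col] = df[col] / pos.median()
    return replace(table, df=df)


def quantify_contrast(
    tables: list[PSMTable],
    contrast: ContrastSpec,
    median_center: bool = False,
) -> pd.DataFrame:
    """Full protein-level quantitation of one contrast across replicate pools.

    Returns one row per protein with columns ``protein_id``,
    ``fc_pool1..fc_poolR`` (per-pool median-ratio fold changes),
    ``fc_geomean`` (defined only when the protein is quantified in all pools),
    ``n_peptides`` (total unique-peptide measurements across pools),
    ``p_value`` (pooled paired t-test, defined for >= 2 measurements) and
    ``quantified_in_all_pools``.
    """
    if not tables:
        raise DataError("no PSM tables supplied")
    pool_ids = [t.pool_id for t in tables]
    if len(set(pool_ids)) != len(pool_ids):
        raise DataError(f"duplicate pool ids: {pool_ids}")
    if median_center:
        tables = [_median_center(t) for t in tables]

    ratio_frames = [peptide_ratios(t, contrast) for t in tables]
    fc = pd.DataFrame(
        {
            f"fc_pool{i}": protein_quantity(rf)
            for i, rf in enumerate(ratio_frames, start=1)
        }
    )
    all_ratios = pd.concat(ratio_frames, ignore_index=True)
    if len(all_ratios):
        counts = all_ratios.groupby("protein_id")["ratio"].size()
        pvals = all_ratios.groupby("protein_id")["ratio"].apply(
            lambda r: protein_pvalue(np.log2(r.to_numpy()))
        )
    else:
        counts = pd.Series(dtype=int)
        pvals = pd.Series(dtype=float)

    complete = fc.notna().all(axis=1)
    fc_cols = list(fc.columns)
    geomean = fc.prod(axis=1) ** (1.0 / len(tables))
    geomean[~complete] = np.nan

    out = fc.copy()
    out["fc_geomean"] = geomean
    out["n_peptides"] = counts.reindex(out.index).fillna(0).astype(int)
    out["p_value"] = pvals.reindex(out.index)
    out["quantified_in_all_pools"] = complete
    out = out.sort_index().rename_axis("protein_id").reset_index()
    out.attrs["contrast"] = contrast.name
    out.attrs["pool_ids"] = pool_ids
    out.attrs["fc_columns"] = fc_cols
    return out
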