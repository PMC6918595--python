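"""Orthogonal validation statistics.

Three independent checks of the reporter-ion results:

* **Western-blot densitometry** — band intensities normalized per lane to a
  housekeeping protein (actin), then scaled so the reference group's mean is
  1; one-way ANOVA across groups with significance stars.
* **WB vs reporter-ion fold-change correlation** — Pearson correlation of the
  fold changes measured by the two methods over matched (protein, contrast)
  pairs.
* **Fetal-loss arithmetic** — percentage loss in viable-fetus counts from an
  early- to a late-gestation group, with group means and population SDs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)

DENSITOMETRY_COLUMNS = ["protein", "group", "lane", "band_intensity", "actin_intensity"]
FETAL_COLUMNS = ["group", "sow_id", "viable_fetuses"]


def read_densitometry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DENSITOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


def read_fetal_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FETAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


def wb_relative_expression(
    table: pd.DataFrame, reference_group: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Actin-normalized relative expression from band densitometry.

    Per lane: ``band / actin``; per protein, all lane values are then divided
    by the mean of the reference group (first group in table order unless
    given), so the reference group's mean is exactly 1.  Lanes with
    non-positive actin are excluded with a warning.

    Returns ``(values, summary)``: per-lane relative values, and per
    protein x group mean, SEM (ddof=1) and n.
    """
    df = table.copy()
    bad = ~(df["actin_intensity"] > 0)
    if bad.any():
        logger.warning("excluding %d lane(s) with non-positive actin intensity", int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise DataError("no valid densitometry lanes")
    df["norm"] = df["band_intensity"] / df["actin_intensity"]

    values_rows = []
    for protein, sub in df.groupby("protein", sort=False):
        groups = list(dict.fromkeys(sub["group"]))
        ref = reference_group if reference_group is not None else groups[0]
        if ref not in groups:
            raise DataError(f"reference group {ref!r} absent for protein {protein!r}")
        ref_mean = sub.loc[sub["group"] == ref, "norm"].mean()
        if not ref_mean > 0:
            raise DataError(f"non-positive reference mean for protein {protein!r}")
        out = sub.copy()
        out["rel_expression"] = out["norm"] / ref_mean
        out["reference_group"] = ref
        values_rows.append(out)
    values = pd.concat(values_rows, ignore_index=True)[
        ["protein", "group", "lane", "rel_expression", "reference_group"]
    ]
    summary = (
        values.groupby(["protein", "group"], sort=False)["rel_expression"]
        .agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else np.nan, n="size")
        .reset_index()
    )
    return values, summary


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def wb_anova(values: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of relative expression across groups, per protein.

    Requires >= 2 groups with >= 2 lanes each.  Degenerate case of zero
    within-group variance everywhere: p = 0 if the group means differ
    (perfectly separated groups), p = 1 if all values are identical.
    """
    rows = []
    for protein, sub in values.groupby("protein", sort=False):
        groups = [g["rel_expression"].to_numpy(float) for _, g in sub.groupby("group", sort=False)]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise DataError(
                f"protein {protein!r}: ANOVA needs >= 2 groups with >= 2 lanes each"
            )
        if all(np.ptp(g) == 0 for g in groups):
            means = [g[0] for g in groups]
            p = 0.0 if np.ptp(means) > 0 else 1.0
            logger.info("protein %r: zero within-group variance, p = %g by convention", protein, p)
        else:
            p = float(stats.f_oneway(*groups).pvalue)
        rows.append({"protein": protein, "p_value": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows, columns=["protein", "p_value", "stars"])


def fc_correlation(
    wb_fc: Sequence[float], itraq_fc: Sequence[float], log2: bool = False
) -> tuple[float, float, int]:
    """Pearson correlation of matched fold changes from the two assays.

    Pairs with a missing value on either side are dropped; at least 3
    complete pairs are required.  ``log2=True`` correlates log2 fold changes
    instead (sensitivity option).
    """
    x = np.asarray(wb_fc, dtype=float)
    y = np.asarray(itraq_fc, dtype=float)
    if x.shape != y.shape:
        raise DataError("fold-change vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DataError(f"need >= 3 matched fold-change pairs, got {x.size}")
    if log2:
        if (x <= 0).any() or (y <= 0).any():
            raise DataError("log2 correlation requires positive fold changes")
        x, y = np.log2(x), np.log2(y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def fetal_loss_rate(
    counts: pd.DataFrame, early_group: str, late_group: str
) -> dict[str, float]:
    """Percent loss in mean viable-fetus count from early to late gestation.

    ``loss_pct = 100 * (mean(early) - mean(late)) / mean(early)``.  SDs use
    the population convention (divisor n), matching summary-style reporting
    of small fixed groups.
    """
    out = {}
    for label, group in (("early", early_group), ("late", late_group)):
        sub = counts.loc[counts["group"] == group, "viable_fetuses"].to_numpy(float)
        if sub.size == 0:
            raise DataError(f"group {group!r} absent or empty in fetal-count table")
        out[f"mean_{label}"] = float(sub.mean())
        out[f"sd_{label}"] = float(sub.std(ddof=0))
        out[f"n_{label}"] = int(sub.size)
    if not out["mean_early"] > 0:
        raise DataError(f"mean count of early group {early_group!r} must be positive")
    out["loss_pct"] = 100.0 * (out["mean_early"] - out["mean_late"]) / out["mean_early"]
    return out
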