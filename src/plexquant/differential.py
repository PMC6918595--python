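"""Differentially-expressed-protein (DEP) calling and per-contrast summaries.

A protein is *increased* when its combined fold change is >= 1.3 and its
p-value < 0.05; *decreased* when the fold change is <= 0.70 with p < 0.05;
otherwise *unchanged*.  The fold-change boundaries are inclusive, the p
boundary strict.  Note the thresholds are intentionally asymmetric:
0.70 < 1/1.3 ~ 0.769, so the down-call is stricter than the reciprocal of the
up-call and must not be symmetrized.

Proteins without a defined p-value or not quantified in every pool are
*ineligible*: they are reported as unchanged with ``eligible = False`` and
kept in the output for auditability, never silently dropped.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

CLASSES = ("increased", "decreased", "unchanged")


def call_deps(
    quant: pd.DataFrame,
    up: float = 1.3,
    down: float = 0.70,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each quantified protein as increased / decreased / unchanged.

    ``quant`` is the output of :func:`plexquant.quant.quantify_contrast`.
    Returns columns ``protein_id``, ``fc_geomean``, ``p_value``,
    ``dep_class``, ``eligible``.
    """
    if up <= 1.0:
        raise ConfigError(f"up threshold must exceed 1, got {up}")
    if down <= 0.0:
        raise ConfigError(f"down threshold must be positive, got {down}")
    if up <= down:
        raise ConfigError(f"up threshold ({up}) must exceed down threshold ({down})")
    if not 0.0 < alpha <= 1.0:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")

    fc = quant["fc_geomean"].to_numpy(dtype=float)
    p = quant["p_value"].to_numpy(dtype=float)
    eligible = quant["quantified_in_all_pools"].to_numpy(bool) & ~np.isnan(p)
    sig = eligible & (p < alpha)
    cls = np.where(
        sig & (fc >= up),
        "increased",
        np.where(sig & (fc <= down), "decreased", "unchanged"),
    )
    out = quant[["protein_id", "fc_geomean", "p_value"]].copy()
    out["dep_class"] = cls
    out["eligible"] = eligible
    out.attrs.update(quant.attrs)
    return out


def summarize_contrasts(
    calls_by_contrast: Mapping[str, pd.DataFrame],
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-contrast DEP counts (increased / decreased / total)."""
    names = list(order) if order is not None else list(calls_by_contrast)
    rows = []
    for name in names:
        calls = calls_by_contrast[name]
        n_inc = int((calls["dep_class"] == "increased").sum())
        n_dec = int((calls["dep_class"] == "decreased").sum())
        rows.append(
            {
                "contrast": name,
                "n_increased": n_inc,
                "n_decreased": n_dec,
                "n_total": n_inc + n_dec,
            }
        )
    return pd.DataFrame(rows, columns=["contrast", "n_increased", "n_decreased", "n_total"])


def dep_ids(calls: pd.DataFrame) -> set[str]:
    """The set of protein ids called as DEPs (class != unchanged)."""
    return set(calls.loc[calls["dep_class"] != "unchanged", "protein_id"])
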