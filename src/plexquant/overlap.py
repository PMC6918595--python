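"""Cross-contrast set analysis: Venn region membership and direction
concordance of DEPs shared between two contrasts.

A protein called as a DEP in both of two contrasts is labeled
``both_increased``, ``both_decreased``, or ``reverse`` (opposite directions) —
the classification used to find reverse-pattern proteins between breeds and
the shared-decreased cluster between contrasts.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError

CONCORDANCE_LABELS = ("both_increased", "both_decreased", "reverse")


def venn_regions(id_sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], list[str]]:
    """Exclusive Venn regions for 2-4 named sets.

    Keys are sorted tuples of the set names whose exact intersection (minus
    all other sets) the region is; only non-empty regions are returned.
    """
    names = list(id_sets)
    if not 2 <= len(names) <= 4:
        raise ConfigError(f"venn analysis supports 2-4 sets, got {len(names)}")
    sets = {n: set(id_sets[n]) for n in names}
    regions: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if r < len(names) else set()
            members = inside - outside
            if members:
                regions[tuple(sorted(combo))] = sorted(members)
    return regions


def venn_counts(id_sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Counts of the non-empty exclusive Venn regions of 2-4 named sets."""
    return {k: len(v) for k, v in venn_regions(id_sets).items()}


def classify_shared_deps(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    name_a: str = "A",
    name_b: str = "B",
) -> pd.DataFrame:
    """Direction-concordance classification of DEPs shared by two contrasts.

    ``calls_a``/``calls_b`` are outputs of :func:`plexquant.differential.call_deps`.
    Returns one row per shared DEP with columns ``protein_id``,
    ``class_<name_a>``, ``class_<name_b>``, ``concordance``.
    """
    da = dict(
        zip(calls_a["protein_id"], calls_a["dep_class"]),
    )
    db = dict(zip(calls_b["protein_id"], calls_b["dep_class"]))
    da = {p: c for p, c in da.items() if c != "unchanged"}
    db = {p: c for p, c in db.items() if c != "unchanged"}
    shared = sorted(set(da) & set(db))
    rows = []
    for p in shared:
        ca, cb = da[p], db[p]
        if ca == cb == "increased":
            label = "both_increased"
        elif ca == cb == "decreased":
            label = "both_decreased"
        else:
            label = "reverse"
        rows.append(
            {"protein_id": p, f"class_{name_a}": ca, f"class_{name_b}": cb, "concordance": label}
        )
    return pd.DataFrame(
        rows, columns=["protein_id", f"class_{name_a}", f"class_{name_b}", "concordance"]
    )


def venn_counts_frame(id_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Venn regions as a tidy frame (region, count, members) for TSV output."""
    regions = venn_regions(id_sets)
    rows = [
        {"region": "&".join(combo), "count": len(members), "members": ";".join(members)}
        for combo, members in sorted(regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["region", "count", "members"])
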