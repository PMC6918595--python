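"""Two-tailed Fisher's exact term enrichment of a DEP set against the
quantified background.

For each term, the 2x2 table is

    =============  ==========  =============
                   with term   without term
    DEP            a           b
    non-DEP        c           d
    =============  ==========  =============

with the background fixed to the commonly quantified protein set (the
analogue of "all identified proteins").  The two-tailed p-value uses the
probability-mass rule: with all margins fixed, sum the hypergeometric
probabilities of every table whose probability does not exceed the observed
table's.  The computation is exact integer arithmetic (binomial-coefficient
weights compared as integers), so ties are decided exactly rather than by
floating-point coincidence.

Benjamini-Hochberg adjusted p-values are reported alongside, but top-term
selection uses the raw p < 0.05, matching a workflow without multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError

NAMESPACES = ("BP", "MF", "CC", "PATHWAY")

#: Default top-k per namespace for reporting.
DEFAULT_TOP_K = {"BP": 15, "PATHWAY": 5}


@dataclass
class AnnotationMap:
    """Protein -> term annotations plus term metadata (namespace, name)."""

    protein_to_terms: dict[str, frozenset[str]]
    terms: dict[str, tuple[str, str]]  # term_id -> (namespace, name)

    def proteins_for(self, term_id: str) -> set[str]:
        return {p for p, ts in self.protein_to_terms.items() if term_id in ts}

    def term_to_proteins(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {t: set() for t in self.terms}
        for p, ts in self.protein_to_terms.items():
            for t in ts:
                out.setdefault(t, set()).add(p)
        return out

    @classmethod
    def from_tsv(cls, annotation_path: str | Path, terms_path: str | Path) -> "AnnotationMap":
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        for col in ("protein_id", "term_id"):
            if col not in ann.columns:
                raise DataError(f"{annotation_path}: missing column {col!r}")
        meta = pd.read_csv(terms_path, sep="\t", dtype=str)
        for col in ("term_id", "namespace", "name"):
            if col not in meta.columns:
                raise DataError(f"{terms_path}: missing column {col!r}")
        bad_ns = set(meta["namespace"]) - set(NAMESPACES)
        if bad_ns:
            raise DataError(f"{terms_path}: unknown namespace(s) {sorted(bad_ns)}")
        p2t: dict[str, set[str]] = {}
        for p, t in zip(ann["protein_id"], ann["term_id"]):
            p2t.setdefault(p, set()).add(t)
        return cls(
            protein_to_terms={p: frozenset(ts) for p, ts in p2t.items()},
            terms={t: (ns, nm) for t, ns, nm in zip(meta["term_id"], meta["namespace"], meta["name"])},
        )

    def to_tsv(self, annotation_path: str | Path, terms_path: str | Path) -> None:
        rows = [
            {"protein_id": p, "term_id": t}
            for p in sorted(self.protein_to_terms)
            for t in sorted(self.protein_to_terms[p])
        ]
        pd.DataFrame(rows, columns=["protein_id", "term_id"]).to_csv(
            annotation_path, sep="\t", index=False
        )
        meta = pd.DataFrame(
            [{"term_id": t, "namespace": ns, "name": nm} for t, (ns, nm) in sorted(self.terms.items())],
            columns=["term_id", "namespace", "name"],
        )
        meta.to_csv(terms_path, sep="\t", index=False)


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Exact two-tailed Fisher p-value for the 2x2 table [[a, b], [c, d]].

    Probability-mass rule with fixed margins, computed in exact integer
    arithmetic: include every table whose hypergeometric weight
    C(m, x) * C(n-m, K-x) is <= the observed table's weight.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ConfigError(f"table entries must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    m = a + b  # DEP margin
    K = a + c  # with-term margin
    lo = max(0, m + K - n)
    hi = min(m, K)
    w_obs = comb(m, a) * comb(n - m, K - a)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(m, x) * comb(n - m, K - x)
        if w <= w_obs:
            num += w
    return float(Fraction(num, comb(n, K)))


def fisher_enrichment(
    dep_set: Iterable[str],
    background: Iterable[str],
    annotation: AnnotationMap,
) -> pd.DataFrame:
    """Per-term two-tailed Fisher enrichment of ``dep_set`` within ``background``.

    Proteins absent from the annotation map count as annotation-free members
    of b/d so the background margins stay fixed.  Terms annotating no
    background protein are skipped.  Returns columns ``term_id``,
    ``namespace``, ``name``, ``a``, ``b``, ``c``, ``d``, ``odds_ratio``,
    ``p_value``, ``p_adj`` (Benjamini-Hochberg).
    """
    dep = set(dep_set)
    bg = set(background)
    stray = sorted(dep - bg)
    if stray:
        raise DataError(
            f"DEP set is not a subset of the background; offending ids: {', '.join(stray)}"
        )
    n_bg = len(bg)
    n_dep = len(dep)
    t2p = annotation.term_to_proteins()
    rows = []
    for term_id in sorted(annotation.terms):
        namespace, name = annotation.terms[term_id]
        with_term = t2p.get(term_id, set()) & bg
        if not with_term:
            continue  # no background annotation: untestable
        a = len(with_term & dep)
        b = n_dep - a
        c = len(with_term) - a
        d = n_bg - n_dep - c
        if b * c > 0:
            odds = (a * d) / (b * c)
        elif a * d > 0:
            odds = float("inf")
        else:
            odds = float("nan")  # 0/0: undefined
        rows.append(
            {
                "term_id": term_id,
                "namespace": namespace,
                "name": name,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p_value": fisher_exact_two_tailed(a, b, c, d),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "namespace", "name", "a", "b", "c", "d", "odds_ratio", "p_value"],
    )
    if len(out):
        out["p_adj"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def top_terms(
    results: pd.DataFrame,
    namespace: str,
    k: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Top-k enriched terms of one namespace: odds ratio > 1 and raw p < alpha,
    sorted by ascending p, then descending a, then term id."""
    if k is None:
        k = DEFAULT_TOP_K.get(namespace, 10)
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    sub = results[
        (results["namespace"] == namespace)
        & (results["p_value"] < alpha)
        & (results["odds_ratio"] > 1)  # NaN odds ratios excluded
    ]
    sub = sub.sort_values(
        by=["p_value", "a", "term_id"], ascending=[True, False, True], kind="mergesort"
    )
    return sub.head(k).reset_index(drop=True)
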