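"""PSM table ingest: parsing, identification filters, and peptide-uniqueness assignment.

A PSM (peptide-spectrum match) table holds one row per fragmentation spectrum
with the matched peptide sequence, the protein accession(s) it maps to, an ion
score, a q-value (spectrum-level FDR estimate) and one reporter-ion intensity
per isobaric channel.  One table corresponds to one multiplexed replicate pool.

The identification filters follow the common Mascot-style convention: keep a
PSM when its ion score is strictly above 20 and its q-value strictly below 1%.
Peptide uniqueness — the eligibility rule for protein quantitation — is a
property of the peptide *sequence* across the whole experiment: a sequence is
unique iff, over every record in every pool, it maps to exactly one distinct
protein accession.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: The experiment's group -> reporter-channel assignment.
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "MSD72": "127",
    "MSD49": "128",
    "DUD49": "129",
    "DUD72": "130",
}

BASE_COLUMNS = ["spectrum_id", "peptide_sequence", "protein_ids", "ion_score", "qvalue"]


def _validate_channel_map(channel_map: Mapping[str, str]) -> dict[str, str]:
    cm = {str(k): str(v) for k, v in channel_map.items()}
    if len(cm) == 0:
        raise ConfigError("channel map is empty")
    if len(set(cm.values())) != len(cm):
        raise ConfigError(f"channel map is not a bijection: {cm}")
    return cm


@dataclass
class PSMTable:
    """Filtered or raw PSM records for one replicate pool.

    ``df`` columns: the BASE_COLUMNS (``protein_ids`` holds tuples of
    accessions) plus one ``intensity_<tag>`` column per channel, and, after
    :func:`assign_uniqueness`, a boolean ``is_unique`` column.
    """

    df: pd.DataFrame
    pool_id: str
    channel_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))

    def __post_init__(self) -> None:
        self.channel_map = _validate_channel_map(self.channel_map)

    def intensity_column(self, group: str) -> str:
        if group not in self.channel_map:
            raise ConfigError(
                f"group {group!r} not in channel map {sorted(self.channel_map)}"
            )
        return f"intensity_{self.channel_map[group]}"

    @property
    def intensity_columns(self) -> list[str]:
        return [f"intensity_{tag}" for tag in self.channel_map.values()]

    def __len__(self) -> int:
        return len(self.df)


def read_psm_table(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    pool_id: str | None = None,
) -> PSMTable:
    """Parse a tab-separated PSM file.

    Required header: the BASE_COLUMNS plus ``intensity_<tag>`` for every tag in
    ``channel_map``.  The ``protein_ids`` field is ';'-separated.  A blank
    intensity is a missing value (kept as NaN); a non-numeric, non-blank
    intensity makes the row malformed.  Malformed rows (also: non-numeric
    score/q-value, q-value outside [0, 1], empty protein field) are dropped
    with a warning listing their line numbers.
    """
    path = Path(path)
    cm = _validate_channel_map(channel_map or DEFAULT_CHANNEL_MAP)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    intensity_cols = [f"intensity_{tag}" for tag in cm.values()]
    required = BASE_COLUMNS + intensity_cols
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")

    df = pd.DataFrame(index=raw.index)
    df["spectrum_id"] = raw["spectrum_id"].str.strip()
    df["peptide_sequence"] = raw["peptide_sequence"].str.strip()
    df["protein_ids"] = raw["protein_ids"].map(
        lambda s: tuple(p.strip() for p in s.split(";") if p.strip())
    )
    ion_score = pd.to_numeric(raw["ion_score"].str.strip(), errors="coerce")
    qvalue = pd.to_numeric(raw["qvalue"].str.strip(), errors="coerce")
    df["ion_score"] = ion_score
    df["qvalue"] = qvalue

    bad = (
        ion_score.isna()
        | qvalue.isna()
        | ~qvalue.between(0.0, 1.0)
        | (df["protein_ids"].map(len) == 0)
        | (df["peptide_sequence"] == "")
    )
    for col in intensity_cols:
        s = raw[col].str.strip()
        vals = pd.to_numeric(s.mask(s == ""), errors="coerce")
        bad |= (s != "") & vals.isna()  # non-blank but unparseable
        bad |= vals < 0
        df[col] = vals

    if bad.any():
        lines = [str(i + 2) for i in df.index[bad]]  # +2: header + 1-based
        logger.warning(
            "%s: dropped %d malformed row(s) at line(s) %s",
            path, int(bad.sum()), ", ".join(lines),
        )
        df = df[~bad].reset_index(drop=True)

    return PSMTable(df=df, pool_id=pool_id or path.stem, channel_map=cm)


def write_psm_table(table: PSMTable, path: str | Path) -> None:
    """Write a PSM table in the same TSV dialect that :func:`read_psm_table` consumes."""
    out = table.df.copy()
    out["protein_ids"] = out["protein_ids"].map(";".join)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def filter_psms(
    table: PSMTable, min_ion_score: float = 20.0, max_fdr: float = 0.01
) -> PSMTable:
    """Apply the identification filters: ion score strictly > ``min_ion_score``
    and q-value strictly < ``max_fdr``.

    Idempotent; preserves record order; the retained row set is a subset of
    the input.
    """
    df = table.df
    mask = (df["ion_score"] > min_ion_score) & (df["qvalue"] < max_fdr)
    kept = df[mask].reset_index(drop=True)
    logger.info(
        "pool %s: retained %d/%d PSMs (ion_score > %g, qvalue < %g)",
        table.pool_id, len(kept), len(df), min_ion_score, max_fdr,
    )
    if len(df) and not len(kept):
        logger.warning("pool %s: no PSMs pass the identification filters", table.pool_id)
    return replace(table, df=kept)


def assign_uniqueness(tables: PSMTable | Sequence[PSMTable]):
    """Flag each record as unique iff its peptide sequence maps to exactly one
    distinct protein accession across *all* pools jointly.

    The flag is a sequence-level, experiment-wide property: a peptide seen
    with accession P1 in one pool and P2 in another is non-unique everywhere.
    Accepts a single table or a sequence; returns the same shape.
    """
    single = isinstance(tables, PSMTable)
    tlist: list[PSMTable] = [tables] if single else list(tables)
    seq_proteins: dict[str, set[str]] = defaultdict(set)
    for t in tlist:
        for seq, prots in zip(t.df["peptide_sequence"], t.df["protein_ids"]):
            seq_proteins[seq].update(prots)
    out = []
    for t in tlist:
        df = t.df.copy()
        df["is_unique"] = df["peptide_sequence"].map(
            lambda s: len(seq_proteins[s]) == 1
        )
        out.append(replace(t, df=df))
    return out[0] if single else out
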