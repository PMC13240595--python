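"""Benchmark inclusion and similarity-based filtering rules.

A benchmark of previously unseen complexes is assembled by (i) keeping
structures at resolution <= 3.5 A released strictly after a training
cutoff date (2021-09-30 by default), (ii) removing redundant complexes
(first occurrence of each unique sequence tuple wins), and by two
training-set similarity filters on precomputed tables: a complex is
excluded when *all* of its chains show >40% sequence identity to the
corresponding chains of any single training complex, or when its complex
TM-score against any training complex exceeds 0.9.  All inequalities are
strict, matching the rules as stated.  The external alignment tools that
produce the similarity tables are never invoked here — their outputs
arrive as TSV.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from ._errors import TableError, TcrEvalError


@dataclass(frozen=True)
class SampleMeta:
    complex_id: str
    resolution: float  # Angstrom
    release_date: _dt.date
    mhc_class: str = "I"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise TcrEvalError(f"{self.complex_id}: resolution must be positive")


def _parse_date(value: Union[str, _dt.date]) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise TableError(f"malformed ISO-8601 date: {value!r}") from exc


def metas_from_table(df: pd.DataFrame) -> List[SampleMeta]:
    """Columns: complex_id, resolution, release_date[, mhc_class]."""
    out = []
    for row in df.to_dict("records"):
        out.append(SampleMeta(
            complex_id=str(row["complex_id"]),
            resolution=float(row["resolution"]),
            release_date=_parse_date(row["release_date"]),
            mhc_class=str(row.get("mhc_class", "I")),
        ))
    return out


def benchmark_filter(
    metas: Sequence[SampleMeta],
    cutoff_date: Union[str, _dt.date] = "2021-09-30",
    max_resolution: float = 3.5,
) -> List[str]:
    """Ids kept by the resolution and release-date rules.

    Keep iff resolution <= max_resolution and release date strictly after
    the cutoff (a structure released on the cutoff day itself could be in
    training data, so it is excluded).
    """
    cutoff = _parse_date(cutoff_date)
    return [
        m.complex_id
        for m in metas
        if m.resolution <= max_resolution and m.release_date > cutoff
    ]


def sequence_filter(
    table: pd.DataFrame,
    threshold: float = 40.0,
    query_roles: Optional[Dict[str, Set[str]]] = None,
) -> List[str]:
    """Ids kept by the chain-wise sequence-identity rule.

    ``table`` columns: query_complex, train_complex, chain_role,
    percent_identity.  A query is excluded iff some single training
    complex has identity strictly above the threshold on *every* chain
    role of the query (the all-chains conjunction must hold against one
    training complex, not mixed across several).

    ``query_roles`` optionally states each query's own chain-role set
    (defaults to the union of roles the query reports in the table).
    A (query, train) group whose roles are disjoint from the query's
    roles has no corresponding chains (e.g. a class I query against a
    class II training entry) and is treated as non-matching with a
    warning; a group that only partially covers the query's roles is a
    table error.
    """
    required = {"query_complex", "train_complex", "chain_role", "percent_identity"}
    if not required.issubset(table.columns):
        raise TableError(f"similarity table needs columns {sorted(required)}")
    if ((table["percent_identity"] < 0) | (table["percent_identity"] > 100)).any():
        raise TableError("percent_identity outside [0, 100]")

    kept: List[str] = []
    for query, group in table.groupby("query_complex", sort=False):
        if query_roles is not None and query in query_roles:
            roles = set(query_roles[query])
        else:
            roles = set(group["chain_role"])
        excluded = False
        for train, pair in group.groupby("train_complex"):
            pair_roles = set(pair["chain_role"])
            if not (pair_roles & roles):
                warnings.warn(
                    f"({query}, {train}): no corresponding chains, treated as non-matching"
                )
                continue
            if not pair_roles >= roles:
                raise TableError(
                    f"({query}, {train}): roles {sorted(pair_roles)} do not cover "
                    f"query roles {sorted(roles)}"
                )
            hits = pair[pair["chain_role"].isin(roles)]
            if (hits["percent_identity"] > threshold).all():
                excluded = True
                break
        if not excluded:
            kept.append(query)
    return kept


def structure_filter(
    table: pd.DataFrame,
    threshold: float = 0.9,
    all_queries: Optional[Sequence[str]] = None,
) -> List[str]:
    """Ids kept by the complex TM-score rule (exclude iff max TM > threshold).

    ``table`` columns: query_complex, train_complex, tm_score.  Queries in
    ``all_queries`` without any table row are kept with a warning (no
    evidence of similarity).
    """
    required = {"query_complex", "train_complex", "tm_score"}
    if not required.issubset(table.columns):
        raise TableError(f"TM table needs columns {sorted(required)}")
    if ((table["tm_score"] < 0) | (table["tm_score"] > 1)).any():
        raise TableError("tm_score outside [0, 1]")
    max_tm = table.groupby("query_complex")["tm_score"].max()
    kept = [q for q, tm in max_tm.items() if not tm > threshold]
    if all_queries is not None:
        for q in all_queries:
            if q not in max_tm.index:
                warnings.warn(f"{q}: no TM-score rows, kept (no evidence of similarity)")
                kept.append(q)
        kept = [q for q in all_queries if q in set(kept)]
    return kept


def redundancy_filter(
    sequences: Sequence[Tuple[str, Tuple[str, ...]]]
) -> List[str]:
    """Keep the first complex per unique chain-sequence tuple, input order."""
    seen: Set[Tuple[str, ...]] = set()
    kept = []
    for complex_id, seqs in sequences:
        if seqs in seen:
            continue
        seen.add(seqs)
        kept.append(complex_id)
    return kept
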