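"""Confidence-based reranking of candidate predictions and the
confidence <-> accuracy correlation analyses.

A folding model emits K candidate structures per complex with its own
ranking.  Reranking reorders the candidates by a confidence signal (CDR3
pLDDT by default) and the effect is quantified as the change in Top-1
success rate — the fraction of complexes whose first-ranked candidate
reaches at least medium (DockQ >= 0.49) or high (DockQ >= 0.80) quality —
plus a rank/quality consistency statistic (mean Kendall tau-b between the
candidate order and DockQ, our operationalisation of "ranking aligns with
quality").

Ties in the reranking signal are broken by the source model's original
rank, so reranking is deterministic and never demotes the model's own
choice on a tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import CorrelationError, RerankError
from .dockq import CLASS_LOWER_BOUND, EvaluationRecord

#: Signals accepted by :func:`signal_value`; any other key is looked up as a
#: regional pLDDT name (e.g. "CDR3A", "TCR").
GLOBAL_SIGNALS = ("ranking_score", "iptm", "ptm")


def signal_value(record: EvaluationRecord, key: str) -> float:
    """Extract a confidence signal from a record; missing -> RerankError."""
    if key in ("CDR3_pLDDT", "CDR3"):
        v = record.plddt.get("CDR3")
    elif key in GLOBAL_SIGNALS:
        v = getattr(record, key)
    else:
        v = record.plddt.get(key)
    if v is None:
        raise RerankError(
            f"signal {key!r} missing on candidate {record.candidate_id!r} "
            f"of {record.complex_id!r}"
        )
    return float(v)


@dataclass
class CandidateSet:
    """K candidate predictions of one complex with their original ranks."""

    complex_id: str
    candidates: List[EvaluationRecord]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise RerankError(f"{self.complex_id}: empty candidate set")
        ranks = sorted(c.original_rank for c in self.candidates)
        if ranks != list(range(1, len(self.candidates) + 1)):
            raise RerankError(
                f"{self.complex_id}: original ranks {ranks} are not a permutation of 1..K"
            )

    def __len__(self) -> int:
        return len(self.candidates)

    def ordered(self, ordering: str = "original", key: Optional[str] = None) -> List[EvaluationRecord]:
        """Candidates under an ordering: original | reranked | oracle."""
        if ordering == "original":
            return sorted(self.candidates, key=lambda c: c.original_rank)
        if ordering == "oracle":
            return sorted(self.candidates, key=lambda c: (-c.dockq, c.original_rank))
        if ordering == "reranked":
            if key is None:
                raise RerankError("reranked ordering needs a signal key")
            return rerank(self, key)
        raise RerankError(f"unknown ordering {ordering!r}")


def rerank(cset: CandidateSet, key: str = "CDR3_pLDDT") -> List[EvaluationRecord]:
    """Candidates sorted descending by signal, ties by original rank."""
    vals = [(signal_value(c, key), c) for c in cset.candidates]
    return [c for _, c in sorted(vals, key=lambda t: (-t[0], t[1].original_rank))]


def top1_success_rate(
    sets: Sequence[CandidateSet],
    ordering: str = "original",
    key: Optional[str] = None,
    threshold_class: str = "medium",
) -> float:
    """Fraction of complexes whose Top-1 candidate reaches the class bound."""
    if not sets:
        raise RerankError("no candidate sets")
    if threshold_class not in ("medium", "high"):
        raise RerankError(f"threshold_class must be medium or high, got {threshold_class!r}")
    bound = CLASS_LOWER_BOUND[threshold_class]
    hits = sum(1 for s in sets if s.ordered(ordering, key)[0].dockq >= bound)
    return hits / len(sets)


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value (n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise CorrelationError(f"need n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def _target_value(record: EvaluationRecord, target: str) -> Optional[float]:
    if target == "DockQ":
        return record.dockq
    if target.endswith("_RMSD"):
        name = target[: -len("_RMSD")]
        res = record.region.get(name)
        return None if res is None else res.rmsd
    if target.endswith("_TM"):
        name = target[: -len("_TM")]
        res = record.region.get(name)
        return None if res is None else res.tm
    raise CorrelationError(f"unknown correlation target {target!r}")


def correlation_matrix(
    records: Sequence[EvaluationRecord],
    signals: Sequence[str] = ("CDR3A", "CDR3B", "CDR3", "TCR", "PEPTIDE", "MHC", "iptm", "ptm"),
    targets: Sequence[str] = ("DockQ", "CDR3_RMSD"),
) -> pd.DataFrame:
    """Pearson r/p table of confidence signals against accuracy targets.

    Rows with undefined correlation (constant input, missing fields) are
    kept and flagged ``n.s.`` with NaN r/p so the table shape is stable.
    """
    rows = []
    for sig in signals:
        for target in targets:
            xs, ys = [], []
            for rec in records:
                try:
                    x = signal_value(rec, sig)
                except RerankError:
                    continue
                y = _target_value(rec, target)
                if y is None:
                    continue
                xs.append(x)
                ys.append(y)
            try:
                r, p = pearson(xs, ys)
                stars = significance_stars(p)
            except CorrelationError:
                r, p, stars = float("nan"), float("nan"), "n.s."
            rows.append({"signal": sig, "target": target, "n": len(xs),
                         "r": r, "p": p, "significance": stars})
    return pd.DataFrame(rows, columns=["signal", "target", "n", "r", "p", "significance"])


def rank_quality_consistency(
    sets: Sequence[CandidateSet],
    ordering: str = "original",
    key: Optional[str] = None,
) -> float:
    """Mean Kendall tau-b between candidate rank (1 = best) and -DockQ.

    +1 means the ordering perfectly tracks docking quality.  Sets whose
    DockQ values are all tied carry no signal and are skipped with a
    warning.
    """
    taus = []
    for s in sets:
        if len(s) < 2:
            raise RerankError(f"{s.complex_id}: consistency needs K >= 2")
        ordered = s.ordered(ordering, key)
        dockqs = np.asarray([c.dockq for c in ordered], dtype=float)
        if np.ptp(dockqs) == 0:
            warnings.warn(f"{s.complex_id}: all DockQ tied, skipped in consistency")
            continue
        ranks = np.arange(1, len(ordered) + 1)
        tau, _ = stats.kendalltau(ranks, -dockqs)
        taus.append(tau)
    if not taus:
        raise RerankError("no candidate set with DockQ variation")
    return float(np.mean(taus))


@dataclass
class RerankReport:
    """Before/after comparison for one reranking signal."""

    key: str
    success_before: Dict[str, float] = field(default_factory=dict)
    success_after: Dict[str, float] = field(default_factory=dict)
    consistency_before: Optional[float] = None
    consistency_after: Optional[float] = None
    top1_delta: Dict[str, float] = field(default_factory=dict)  # complex -> after - before

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in ("medium", "high"):
            rows.append({
                "metric": f"top1_success_{cls}",
                "before": self.success_before.get(cls),
                "after": self.success_after.get(cls),
                "delta": self.success_after.get(cls, np.nan) - self.success_before.get(cls, np.nan),
            })
        rows.append({
            "metric": "rank_quality_consistency",
            "before": self.consistency_before,
            "after": self.consistency_after,
            "delta": (None if self.consistency_before is None or self.consistency_after is None
                      else self.consistency_after - self.consistency_before),
        })
        return pd.DataFrame(rows)


def build_rerank_report(sets: Sequence[CandidateSet], key: str = "CDR3_pLDDT") -> RerankReport:
    report = RerankReport(key=key)
    for cls in ("medium", "high"):
        report.success_before[cls] = top1_success_rate(sets, "original", threshold_class=cls)
        report.success_after[cls] = top1_success_rate(sets, "reranked", key, threshold_class=cls)
    for s in sets:
        before = s.ordered("original")[0].dockq
        after = s.ordered("reranked", key)[0].dockq
        report.top1_delta[s.complex_id] = after - before
    if all(len(s) >= 2 for s in sets):
        try:
            report.consistency_before = rank_quality_consistency(sets, "original")
            report.consistency_after = rank_quality_consistency(sets, "reranked", key)
        except RerankError:
            pass
    return report


def sets_from_records(records: Sequence[EvaluationRecord]) -> List[CandidateSet]:
    """Group evaluation records into candidate sets by complex id."""
    by_complex: Dict[str, List[EvaluationRecord]] = {}
    for rec in records:
        by_complex.setdefault(rec.complex_id, []).append(rec)
    return [CandidateSet(cid, cands) for cid, cands in by_complex.items()]
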