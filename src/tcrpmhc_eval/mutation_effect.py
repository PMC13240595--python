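"""Direction concordance between confidence changes and binding-affinity
changes (ddG) for CDR3 point mutations.

Convention: ddG = dG(mutant) - dG(wild-type), so negative ddG means the
mutation *increases* binding affinity.  A confidence signal is concordant
with a mutation when it moves opposite to ddG:

    concordant  <=>  (ddG < 0 and dSignal > 0) or (ddG > 0 and dSignal < 0)

A flat signal (dSignal = 0) fails to reflect the change and counts as
non-concordant; ddG = 0 pairs have no defined direction and are excluded
with a warning.  Summaries are reported per ddG direction and pooled, and
several datasets pool by summing counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from ._errors import ConfidenceError, TcrEvalError


@dataclass
class MutationPair:
    """A wild-type/mutant pair with ddG and confidence signals."""

    pair_id: str
    complex_id: str
    chain: str  # "A" or "B" (TCR chain carrying the mutation)
    imgt_position: int
    wt_aa: str
    mut_aa: str
    ddg: float  # kcal/mol, dG_mut - dG_wt
    wt_signals: Dict[str, float] = field(default_factory=dict)
    mut_signals: Dict[str, float] = field(default_factory=dict)
    dataset: str = ""

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.wt_aa}{self.imgt_position}{self.mut_aa}"


def delta_confidence(pair: MutationPair, signal: str = "CDR3_pLDDT") -> float:
    """signal(mutant) - signal(wild-type)."""
    for side, signals in (("wild-type", pair.wt_signals), ("mutant", pair.mut_signals)):
        if signal not in signals:
            raise ConfidenceError(f"pair {pair.pair_id}: signal {signal!r} missing on {side}")
    return pair.mut_signals[signal] - pair.wt_signals[signal]


@dataclass
class DirectionCounts:
    n_concordant: int = 0
    n_total: int = 0


@dataclass
class ConcordanceSummary:
    """Per-direction and pooled concordance counts."""

    signal: str
    negative: DirectionCounts = field(default_factory=DirectionCounts)  # ddG < 0
    positive: DirectionCounts = field(default_factory=DirectionCounts)  # ddG > 0
    n_excluded: int = 0
    dataset: str = ""
    breakdown: List["ConcordanceSummary"] = field(default_factory=list)

    @property
    def n_concordant(self) -> int:
        return self.negative.n_concordant + self.positive.n_concordant

    @property
    def n_total(self) -> int:
        return self.negative.n_total + self.positive.n_total

    @property
    def percentage(self) -> float:
        if self.n_total == 0:
            raise TcrEvalError("concordance undefined on zero pairs")
        return 100.0 * self.n_concordant / self.n_total

    @classmethod
    def from_counts(
        cls,
        signal: str,
        neg_concordant: int,
        neg_total: int,
        pos_concordant: int,
        pos_total: int,
        dataset: str = "",
    ) -> "ConcordanceSummary":
        return cls(
            signal=signal,
            negative=DirectionCounts(neg_concordant, neg_total),
            positive=DirectionCounts(pos_concordant, pos_total),
            dataset=dataset,
        )

    @classmethod
    def pool(cls, summaries: Sequence["ConcordanceSummary"]) -> "ConcordanceSummary":
        """Pool datasets by summing per-direction counts."""
        if not summaries:
            raise TcrEvalError("nothing to pool")
        signals = {s.signal for s in summaries}
        if len(signals) > 1:
            raise TcrEvalError(f"cannot pool different signals: {sorted(signals)}")
        out = cls(signal=summaries[0].signal, dataset="pooled", breakdown=list(summaries))
        for s in summaries:
            out.negative.n_concordant += s.negative.n_concordant
            out.negative.n_total += s.negative.n_total
            out.positive.n_concordant += s.positive.n_concordant
            out.positive.n_total += s.positive.n_total
            out.n_excluded += s.n_excluded
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for summ in (self.breakdown or [self]):
            rows.append({
                "dataset": summ.dataset or "all", "signal": summ.signal,
                "neg_concordant": summ.negative.n_concordant, "neg_total": summ.negative.n_total,
                "pos_concordant": summ.positive.n_concordant, "pos_total": summ.positive.n_total,
                "n_concordant": summ.n_concordant, "n_total": summ.n_total,
                "percentage": summ.percentage if summ.n_total else float("nan"),
            })
        if self.breakdown:
            rows.append({
                "dataset": "pooled", "signal": self.signal,
                "neg_concordant": self.negative.n_concordant, "neg_total": self.negative.n_total,
                "pos_concordant": self.positive.n_concordant, "pos_total": self.positive.n_total,
                "n_concordant": self.n_concordant, "n_total": self.n_total,
                "percentage": self.percentage,
            })
        return pd.DataFrame(rows)


def is_concordant(ddg: float, delta: float) -> bool:
    """Sign rule: confidence must move against ddG; a flat signal fails."""
    return (ddg < 0 and delta > 0) or (ddg > 0 and delta < 0)


def concordance(
    pairs: Sequence[MutationPair],
    signal: str = "CDR3_pLDDT",
    dataset: str = "",
) -> ConcordanceSummary:
    """Direction-concordance summary over a set of mutation pairs."""
    summary = ConcordanceSummary(signal=signal, dataset=dataset)
    for pair in pairs:
        if pair.ddg == 0:
            warnings.warn(f"pair {pair.pair_id}: ddG = 0, direction undefined, excluded")
            summary.n_excluded += 1
            continue
        delta = delta_confidence(pair, signal)
        side = summary.negative if pair.ddg < 0 else summary.positive
        side.n_total += 1
        if is_concordant(pair.ddg, delta):
            side.n_concordant += 1
    if summary.n_total == 0:
        raise TcrEvalError("all mutation pairs excluded (ddG = 0 throughout)")
    return summary


def pairs_from_table(df: pd.DataFrame, signal_columns: Sequence[str]) -> List[MutationPair]:
    """Build pairs from a mutation TSV.

    Expected columns: pair_id, complex_id, chain, imgt_position, wt_aa,
    mut_aa, ddg, and for each signal S the pair ``wt_<S>`` / ``mut_<S>``.
    An optional ``dataset`` column labels the per-dataset breakdown.
    """
    pairs = []
    for row in df.to_dict("records"):
        wt = {s: float(row[f"wt_{s}"]) for s in signal_columns if f"wt_{s}" in row}
        mut = {s: float(row[f"mut_{s}"]) for s in signal_columns if f"mut_{s}" in row}
        pairs.append(MutationPair(
            pair_id=str(row["pair_id"]),
            complex_id=str(row["complex_id"]),
            chain=str(row["chain"]),
            imgt_position=int(row["imgt_position"]),
            wt_aa=str(row["wt_aa"]),
            mut_aa=str(row["mut_aa"]),
            ddg=float(row["ddg"]),
            wt_signals=wt,
            mut_signals=mut,
            dataset=str(row.get("dataset", "")),
        ))
    return pairs
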