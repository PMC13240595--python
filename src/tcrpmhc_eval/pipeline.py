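"""Cohort-level orchestration: manifest -> evaluation records -> reports.

The manifest TSV lists one row per (complex, candidate) with paths to the
native PDB, the prediction PDB, the confidence JSON, the chain role map
and the IMGT numbering table.  Evaluation is isolated per row: a corrupt
file logs a failure and the run continues; the run only fails when zero
rows succeed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from ._errors import TcrEvalError
from .confidence import apply_confidence, read_confidence
from .dockq import (
    EvalConfig,
    EvaluationRecord,
    evaluate_pair,
    frame_to_records,
    records_to_frame,
)
from .mutation_effect import ConcordanceSummary, concordance, pairs_from_table
from .reranking import RerankReport, build_rerank_report, correlation_matrix, sets_from_records
from .structures import assign_roles, attach_numbering, pair_residues, read_structure

logger = logging.getLogger("tcrpmhc_eval")

MANIFEST_COLUMNS = (
    "complex_id", "candidate_id", "native", "prediction", "confidence",
    "original_rank", "role_map", "numbering",
)


def load_manifest(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise TcrEvalError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["complex_id", "candidate_id"])
    if dup.any():
        raise TcrEvalError("manifest has duplicate (complex_id, candidate_id) rows")
    # relative paths resolve against the manifest's own directory
    base = Path(path).resolve().parent
    for col in ("native", "prediction", "confidence", "role_map", "numbering"):
        df[col] = [
            str(v) if (not isinstance(v, str)) or Path(v).is_absolute() else str(base / v)
            for v in df[col]
        ]
    return df


def _load_role_map(path: Union[str, Path]) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["chain_id"], df["role"]))


def evaluate_manifest(
    manifest: pd.DataFrame,
    config: Optional[EvalConfig] = None,
) -> Tuple[List[EvaluationRecord], List[Dict[str, str]]]:
    """Evaluate every manifest row; returns (records, per-row failures)."""
    config = config or EvalConfig()
    records: List[EvaluationRecord] = []
    failures: List[Dict[str, str]] = []
    native_cache: Dict[str, object] = {}
    for row in manifest.to_dict("records"):
        cid, cand = str(row["complex_id"]), str(row["candidate_id"])
        try:
            mhc_class = str(row.get("mhc_class", "I"))
            key = str(row["native"])
            if key not in native_cache:
                native = read_structure(row["native"], source="native")
                assign_roles(native, _load_role_map(row["role_map"]), mhc_class)
                attach_numbering(native, row["numbering"])
                native_cache[key] = native
            native = native_cache[key]
            pred = read_structure(row["prediction"], source="prediction")
            assign_roles(pred, _load_role_map(row["role_map"]), mhc_class)
            bundle = None
            conf = row.get("confidence")
            if isinstance(conf, str) and conf and conf.lower() != "nan":
                bundle = read_confidence(conf)
                apply_confidence(pred, bundle)
            corr = pair_residues(native, pred)
            rec = evaluate_pair(
                native, pred, corr, config,
                complex_id=cid, candidate_id=cand,
                original_rank=int(row["original_rank"]),
                bundle=bundle,
            )
            records.append(rec)
            logger.info("evaluate %s/%s: dockq=%.3f class=%s", cid, cand,
                        rec.dockq, rec.quality_class)
        except (TcrEvalError, OSError, ValueError) as exc:
            logger.warning("evaluate %s/%s failed: %s", cid, cand, exc)
            failures.append({"complex_id": cid, "candidate_id": cand, "error": str(exc)})
    if not records:
        raise TcrEvalError("no manifest row evaluated successfully")
    return records, failures


def run_evaluate(
    manifest_path: Union[str, Path],
    out_path: Union[str, Path],
    config: Optional[EvalConfig] = None,
) -> pd.DataFrame:
    manifest = load_manifest(manifest_path)
    records, failures = evaluate_manifest(manifest, config)
    df = records_to_frame(records)
    df.to_csv(out_path, sep="\t", index=False, float_format="%.6f")
    if failures:
        fail_path = Path(out_path).with_suffix(".failures.tsv")
        pd.DataFrame(failures).to_csv(fail_path, sep="\t", index=False)
    return df


def load_records(path: Union[str, Path]) -> List[EvaluationRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))


def run_rerank_report(
    records_path: Union[str, Path],
    key: str = "CDR3_pLDDT",
) -> RerankReport:
    sets = sets_from_records(load_records(records_path))
    return build_rerank_report(sets, key)


def run_correlations(
    records_path: Union[str, Path],
    signals: Optional[Sequence[str]] = None,
    targets: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    records = load_records(records_path)
    kwargs = {}
    if signals:
        kwargs["signals"] = tuple(signals)
    if targets:
        kwargs["targets"] = tuple(targets)
    return correlation_matrix(records, **kwargs)


def run_concordance(
    mutation_table: Union[str, Path, pd.DataFrame],
    signal: str = "CDR3_pLDDT",
) -> ConcordanceSummary:
    if not isinstance(mutation_table, pd.DataFrame):
        mutation_table = pd.read_csv(mutation_table, sep="\t")
    pairs = pairs_from_table(mutation_table, (signal,))
    datasets = sorted({p.dataset for p in pairs})
    if len(datasets) > 1:
        parts = [
            concordance([p for p in pairs if p.dataset == ds], signal, dataset=ds)
            for ds in datasets
        ]
        return ConcordanceSummary.pool(parts)
    return concordance(pairs, signal, dataset=datasets[0] if datasets else "")
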