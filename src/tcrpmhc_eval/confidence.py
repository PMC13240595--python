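"""Prediction confidence metadata: per-residue pLDDT and global scores.

Folding models report a per-residue confidence (pLDDT, 0-100), a global
predicted TM-score (pTM), an interface-focused variant (ipTM) and an
opaque ranking score.  This module reads a small JSON sidecar file with
those fields, reconciles JSON pLDDT with B-factor-derived pLDDT, and
computes regional aggregates.  The regional pLDDT of a residue set is the
plain arithmetic mean over all residues in the set; in particular the CDR3
pLDDT pools the CDR3-alpha and CDR3-beta residues into one mean (not a
mean of the two per-loop means).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np

from ._errors import ConfidenceError
from .regions import RegionSpec
from .structures import RoledComplex, autoscale_plddt, select_region


@dataclass
class ConfidenceBundle:
    """Confidence metadata for one predicted structure."""

    per_residue_plddt: Dict[Tuple[str, int], float] = field(default_factory=dict)
    ptm: Optional[float] = None
    iptm: Optional[float] = None
    ranking_score: Optional[float] = None
    source: str = "json"


def read_confidence(path: Union[str, Path]) -> ConfidenceBundle:
    """Read a confidence JSON sidecar.

    Schema (all keys optional)::

        {"plddt": {"<chain_id>": [per-residue values...], ...},
         "ptm": 0.9, "iptm": 0.85, "ranking_score": 0.88}

    pLDDT lists are indexed by residue ordinal within the chain and are
    subject to the 0-1 -> 0-100 auto-scale rule.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfidenceError(f"cannot read confidence file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfidenceError(f"{path}: top level must be a JSON object")
    bundle = ConfidenceBundle()
    for key in ("ptm", "iptm", "ranking_score"):
        if data.get(key) is not None:
            setattr(bundle, key, float(data[key]))
    plddt = data.get("plddt")
    if plddt is not None:
        if not isinstance(plddt, dict):
            raise ConfidenceError(f"{path}: 'plddt' must map chain id -> list")
        for chain_id, values in plddt.items():
            try:
                scaled = autoscale_plddt(values, context=f"{path} chain {chain_id}")
            except Exception as exc:
                raise ConfidenceError(str(exc)) from exc
            for i, v in enumerate(scaled):
                bundle.per_residue_plddt[(str(chain_id), i)] = v
    return bundle


def apply_confidence(c: RoledComplex, bundle: ConfidenceBundle) -> RoledComplex:
    """Attach bundle pLDDT to a complex's residues.

    JSON pLDDT wins over B-factor-derived pLDDT already on the structure;
    if the two disagree by more than 1.0 anywhere, a consistency warning is
    emitted.  The pLDDT list length must match the chain residue count.
    """
    if bundle.per_residue_plddt:
        per_chain: Dict[str, int] = {}
        for (chain_id, _idx) in bundle.per_residue_plddt:
            per_chain[chain_id] = per_chain.get(chain_id, 0) + 1
        for chain_id, n in per_chain.items():
            ch = c.chain_by_id(chain_id)
            if n != len(ch):
                raise ConfidenceError(
                    f"chain {chain_id!r}: pLDDT list length {n} != residue count {len(ch)}"
                )
        max_diff = 0.0
        for ch in c.chains:
            for r in ch.residues:
                key = (ch.chain_id, r.position_index)
                if key in bundle.per_residue_plddt:
                    v = bundle.per_residue_plddt[key]
                    if r.plddt is not None:
                        max_diff = max(max_diff, abs(r.plddt - v))
                    r.plddt = v
        if max_diff > 1.0:
            warnings.warn(
                f"JSON pLDDT and B-factor pLDDT disagree (max |diff| = {max_diff:.2f}); "
                "JSON values kept"
            )
    return c


def region_plddt(c: RoledComplex, spec: RegionSpec) -> float:
    """Unweighted mean pLDDT over all residues the region selects."""
    residues = select_region(c, spec)
    values = []
    for r in residues:
        if r.plddt is None:
            raise ConfidenceError(
                f"residue {r.chain_id}:{r.author_seq_id} in region {spec.name!r} has no pLDDT"
            )
        values.append(r.plddt)
    return float(np.mean(values))
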