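"""Two-body interface quality: Fnat, iRMS, LRMS, DockQ and CAPRI classes.

The complex is reduced to two rigid bodies — by default the TCR (alpha +
beta chains) as receptor and the pMHC (peptide + MHC chains) as ligand —
and scored with the standard interface-quality components:

* **Fnat** — fraction of native cross-body residue contacts preserved in
  the prediction.  A contact is any residue pair with an inter-atomic
  distance below the cutoff (all-atom 5 A, or C-alpha-only 8 A when only
  C-alpha coordinates exist).
* **iRMS** — C-alpha RMSD over the native-defined interface residues
  (members of any cross-body pair within 10 A) after superposing on those
  residues.
* **LRMS** — C-alpha RMSD of the ligand after superposing the receptor.

These combine into DockQ::

    DockQ = (Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3

calibrated against the CAPRI categories: incorrect (DockQ < 0.23),
acceptable (0.23 <= DockQ < 0.49), medium (0.49 <= DockQ < 0.80) and high
(DockQ >= 0.80).

:func:`evaluate_pair` composes these with the superposition metrics and
regional pLDDT into one :class:`EvaluationRecord` per native/prediction
pair; the same machinery scores the pMHC sub-complex by swapping in a
``BodySplit`` of MHC versus peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._errors import (
    ConfidenceError,
    DomainError,
    EmptyRegionError,
    GeometryError,
    SplitError,
    UndefinedInterfaceError,
)
from .confidence import ConfidenceBundle, region_plddt
from .regions import MHC_ROLES, RegionSpec, Role, TCR_ROLES, default_regions
from .structures import CorrespondenceMap, Residue, RoledComplex
from .superpose import TmScoreResult, kabsch, region_metrics, rmsd, tm_score

#: DockQ component distance scales (from the DockQ reference definition).
IRMS_SCALE = 1.5
LRMS_SCALE = 8.5
#: Contact cutoffs by atom mode and the interface-definition cutoff for iRMS.
CONTACT_CUTOFFS = {"allatom": 5.0, "ca": 8.0}
INTERFACE_CUTOFF = 10.0

QUALITY_CLASSES = ("incorrect", "acceptable", "medium", "high")
CLASS_LOWER_BOUND = {"acceptable": 0.23, "medium": 0.49, "high": 0.80}


@dataclass(frozen=True)
class BodySplit:
    """Receptor/ligand role partition for the two-body reduction."""

    receptor_roles: FrozenSet[Role] = frozenset({Role.TCRA, Role.TCRB})
    ligand_roles: FrozenSet[Role] = frozenset({Role.PEPTIDE, Role.MHC_A, Role.MHC_B})

    def __post_init__(self) -> None:
        if self.receptor_roles & self.ligand_roles:
            raise SplitError("receptor and ligand role sets overlap")

    def validate(self, c: RoledComplex) -> None:
        # roles outside both bodies are simply ignored (e.g. the TCR when
        # scoring the pMHC sub-complex); both bodies must be non-empty
        present = set(c.roles)
        if not (present & self.receptor_roles) or not (present & self.ligand_roles):
            raise SplitError("a body is empty for this complex")


#: Default TCR-vs-pMHC split and the pMHC sub-complex split (MHC vs peptide).
TCR_PMHC_SPLIT = BodySplit()
PMHC_SPLIT = BodySplit(
    receptor_roles=frozenset({Role.MHC_A, Role.MHC_B}),
    ligand_roles=frozenset({Role.PEPTIDE}),
)


@dataclass
class ContactSet:
    contacts: Set[Tuple[Tuple[str, int], Tuple[str, int]]]
    cutoff: float
    atom_mode: str

    def __len__(self) -> int:
        return len(self.contacts)


def _body_residues(c: RoledComplex, roles: FrozenSet[Role]) -> List[Residue]:
    return [r for r in c.residues(roles & set(c.roles))]


def resolve_atom_mode(native: RoledComplex, pred: RoledComplex, atom_mode: str) -> str:
    """'auto' picks all-atom only when both structures carry full atoms."""
    if atom_mode in ("ca", "allatom"):
        return atom_mode
    if atom_mode != "auto":
        raise ValueError(f"unknown atom mode {atom_mode!r}")
    return "allatom" if (native.has_full_atoms() and pred.has_full_atoms()) else "ca"


def _min_distances(res_a: List[Residue], res_b: List[Residue], atom_mode: str) -> np.ndarray:
    """Pairwise minimal inter-residue distances (len_a x len_b)."""
    if atom_mode == "ca":
        ca_a = np.asarray([r.ca for r in res_a])
        ca_b = np.asarray([r.ca for r in res_b])
        return cdist(ca_a, ca_b)
    # all-atom: flatten atoms, then reduce per residue pair
    out = np.empty((len(res_a), len(res_b)))
    coords_b = [r.all_coords() for r in res_b]
    for i, ra in enumerate(res_a):
        ca = ra.all_coords()
        for j, cb in enumerate(coords_b):
            out[i, j] = cdist(ca, cb).min()
    return out


def interface_contacts(
    c: RoledComplex,
    split: BodySplit = TCR_PMHC_SPLIT,
    atom_mode: str = "ca",
    cutoff: Optional[float] = None,
) -> ContactSet:
    """All cross-body residue pairs with distance strictly below the cutoff."""
    split.validate(c)
    if cutoff is None:
        cutoff = CONTACT_CUTOFFS[atom_mode]
    rec = _body_residues(c, split.receptor_roles)
    lig = _body_residues(c, split.ligand_roles)
    dmat = _min_distances(rec, lig, atom_mode)
    ii, jj = np.nonzero(dmat < cutoff)
    contacts = {(rec[i].key, lig[j].key) for i, j in zip(ii, jj)}
    return ContactSet(contacts=contacts, cutoff=float(cutoff), atom_mode=atom_mode)


def fnat(
    native_contacts: ContactSet,
    pred: RoledComplex,
    corr: CorrespondenceMap,
    split: BodySplit = TCR_PMHC_SPLIT,
    atom_mode: Optional[str] = None,
    cutoff: Optional[float] = None,
) -> float:
    """Fraction of native contacts preserved in the prediction."""
    if len(native_contacts) == 0:
        raise UndefinedInterfaceError("native complex has no cross-body contacts")
    atom_mode = atom_mode or native_contacts.atom_mode
    if cutoff is None:
        cutoff = native_contacts.cutoff
    pred_by_native_key = {nat.key: prd for nat, prd in corr.pairs}
    kept = 0
    for rk, lk in native_contacts.contacts:
        pr, pl = pred_by_native_key[rk], pred_by_native_key[lk]
        if atom_mode == "ca":
            d = float(np.linalg.norm(pr.ca - pl.ca))
        else:
            d = float(cdist(pr.all_coords(), pl.all_coords()).min())
        if d < cutoff:
            kept += 1
    return kept / len(native_contacts)


def native_interface_residues(
    native: RoledComplex,
    split: BodySplit = TCR_PMHC_SPLIT,
    cutoff: float = INTERFACE_CUTOFF,
    atom_mode: str = "ca",
) -> List[Residue]:
    """Native residues in any cross-body pair within ``cutoff`` (both members)."""
    split.validate(native)
    rec = _body_residues(native, split.receptor_roles)
    lig = _body_residues(native, split.ligand_roles)
    dmat = _min_distances(rec, lig, atom_mode)
    ii, jj = np.nonzero(dmat < cutoff)
    keys = {rec[i].key for i in ii} | {lig[j].key for j in jj}
    return [r for r in native.residues() if r.key in keys]


def irms(
    native: RoledComplex,
    pred: RoledComplex,
    corr: CorrespondenceMap,
    split: BodySplit = TCR_PMHC_SPLIT,
    interface_cutoff: float = INTERFACE_CUTOFF,
    atom_mode: str = "ca",
) -> float:
    """Interface C-alpha RMSD after superposing on native interface residues."""
    iface = native_interface_residues(native, split, interface_cutoff, atom_mode)
    if len(iface) < 3:
        raise GeometryError(f"only {len(iface)} native interface residues (need >= 3)")
    fixed, moving = corr.coords(iface)
    return rmsd(fixed, moving, superpose=True)


def lrms(
    native: RoledComplex,
    pred: RoledComplex,
    corr: CorrespondenceMap,
    split: BodySplit = TCR_PMHC_SPLIT,
) -> float:
    """Ligand C-alpha RMSD after superposing the receptor."""
    split.validate(native)
    rec = _body_residues(native, split.receptor_roles)
    lig = _body_residues(native, split.ligand_roles)
    rec_fixed, rec_moving = corr.coords(rec)
    sup = kabsch(rec_fixed, rec_moving)
    lig_fixed, lig_moving = corr.coords(lig)
    return rmsd(lig_fixed, sup.apply(lig_moving), superpose=False)


def dockq_score(fnat_value: float, lrms_value: float, irms_value: float) -> float:
    """Combine the three components into the DockQ score."""
    if not (0.0 <= fnat_value <= 1.0):
        raise DomainError(f"fnat {fnat_value} outside [0, 1]")
    if lrms_value < 0 or irms_value < 0:
        raise DomainError("RMSD components must be non-negative")
    return (
        fnat_value
        + 1.0 / (1.0 + (irms_value / IRMS_SCALE) ** 2)
        + 1.0 / (1.0 + (lrms_value / LRMS_SCALE) ** 2)
    ) / 3.0


def classify_dockq(score: float) -> str:
    """CAPRI-calibrated quality class for a DockQ score."""
    if not (0.0 <= score <= 1.0):
        raise DomainError(f"DockQ {score} outside [0, 1]")
    if score < CLASS_LOWER_BOUND["acceptable"]:
        return "incorrect"
    if score < CLASS_LOWER_BOUND["medium"]:
        return "acceptable"
    if score < CLASS_LOWER_BOUND["high"]:
        return "medium"
    return "high"


@dataclass
class RegionResult:
    rmsd: float
    tm: float


@dataclass
class EvaluationRecord:
    """All metrics for one native/prediction pair."""

    complex_id: str
    candidate_id: str
    original_rank: Optional[int] = None
    atom_mode: str = "ca"
    fnat: Optional[float] = None
    irms: Optional[float] = None
    lrms: Optional[float] = None
    dockq: Optional[float] = None
    quality_class: Optional[str] = None
    global_rmsd: Optional[float] = None
    global_tm: Optional[float] = None
    region: Dict[str, RegionResult] = field(default_factory=dict)
    plddt: Dict[str, float] = field(default_factory=dict)
    ptm: Optional[float] = None
    iptm: Optional[float] = None
    ranking_score: Optional[float] = None

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {
            "complex_id": self.complex_id,
            "candidate_id": self.candidate_id,
            "original_rank": self.original_rank,
            "atom_mode": self.atom_mode,
            "fnat": self.fnat,
            "irms": self.irms,
            "lrms": self.lrms,
            "dockq": self.dockq,
            "quality_class": self.quality_class,
            "global_rmsd": self.global_rmsd,
            "global_tm": self.global_tm,
            "ptm": self.ptm,
            "iptm": self.iptm,
            "ranking_score": self.ranking_score,
        }
        for name, res in self.region.items():
            row[f"rmsd_{name}"] = res.rmsd
            row[f"tm_{name}"] = res.tm
        for name, v in self.plddt.items():
            row[f"plddt_{name}"] = v
        return row

    @classmethod
    def from_row(cls, row: Mapping[str, object]) -> "EvaluationRecord":
        def _f(key: str) -> Optional[float]:
            v = row.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return float(v)  # type: ignore[arg-type]

        rec = cls(
            complex_id=str(row["complex_id"]),
            candidate_id=str(row["candidate_id"]),
            original_rank=(int(row["original_rank"]) if _f("original_rank") is not None else None),
            atom_mode=str(row.get("atom_mode", "ca")),
            fnat=_f("fnat"),
            irms=_f("irms"),
            lrms=_f("lrms"),
            dockq=_f("dockq"),
            quality_class=(str(row["quality_class"]) if row.get("quality_class") else None),
            global_rmsd=_f("global_rmsd"),
            global_tm=_f("global_tm"),
            ptm=_f("ptm"),
            iptm=_f("iptm"),
            ranking_score=_f("ranking_score"),
        )
        for key in row:
            if key.startswith("rmsd_"):
                name = key[len("rmsd_"):]
                r, t = _f(key), _f(f"tm_{name}")
                if r is not None:
                    rec.region[name] = RegionResult(rmsd=r, tm=(t if t is not None else np.nan))
            elif key.startswith("plddt_"):
                v = _f(key)
                if v is not None:
                    rec.plddt[key[len("plddt_"):]] = v
        return rec


@dataclass
class EvalConfig:
    """What :func:`evaluate_pair` computes and how."""

    split: BodySplit = TCR_PMHC_SPLIT
    atom_mode: str = "auto"  # auto | ca | allatom
    cdr_windows: Optional[Mapping[str, Tuple[int, int]]] = None
    #: region name -> superposition frame; None uses the standard catalogue:
    #: whole-chain regions local, CDR regions framework.
    region_frames: Optional[Mapping[str, str]] = None
    #: regions to aggregate pLDDT over; None = CDR3A/CDR3B/CDR3/TCR/PEPTIDE/MHC.
    plddt_regions: Optional[Tuple[str, ...]] = None
    compute_global: bool = True

    def resolved_region_frames(self) -> Dict[str, str]:
        if self.region_frames is not None:
            return dict(self.region_frames)
        return {
            "TCR": "local",
            "PEPTIDE": "local",
            "MHC": "local",
            "CDR3A": "framework",
            "CDR3B": "framework",
            "CDR3": "framework",
        }

    def resolved_plddt_regions(self) -> Tuple[str, ...]:
        if self.plddt_regions is not None:
            return tuple(self.plddt_regions)
        return ("CDR3A", "CDR3B", "CDR3", "TCR", "PEPTIDE", "MHC")


#: Fast configuration for large synthetic cohorts: DockQ + CDR3 quantities only.
FAST_EVAL = EvalConfig(
    region_frames={"CDR3": "framework"},
    plddt_regions=("CDR3",),
    compute_global=False,
)


def evaluate_pair(
    native: RoledComplex,
    pred: RoledComplex,
    corr: CorrespondenceMap,
    config: Optional[EvalConfig] = None,
    complex_id: str = "complex",
    candidate_id: str = "candidate",
    original_rank: Optional[int] = None,
    bundle: Optional[ConfidenceBundle] = None,
) -> EvaluationRecord:
    """Compute the full metric record for one native/prediction pair."""
    config = config or EvalConfig()
    # predictions inherit IMGT numbers from the native through the pairing,
    # so region selection works on both sides
    for nat, prd in corr.pairs:
        if prd.imgt is None:
            prd.imgt = nat.imgt
    mode = resolve_atom_mode(native, pred, config.atom_mode)
    rec = EvaluationRecord(
        complex_id=complex_id, candidate_id=candidate_id,
        original_rank=original_rank, atom_mode=mode,
    )

    native_contacts = interface_contacts(native, config.split, atom_mode=mode)
    rec.fnat = fnat(native_contacts, pred, corr, config.split)
    rec.irms = irms(native, pred, corr, config.split, atom_mode=mode)
    rec.lrms = lrms(native, pred, corr, config.split)
    rec.dockq = dockq_score(rec.fnat, rec.lrms, rec.irms)
    rec.quality_class = classify_dockq(rec.dockq)

    regions = default_regions(config.cdr_windows)
    if config.compute_global:
        fixed, moving = corr.coords()
        rec.global_rmsd = rmsd(fixed, moving, superpose=True)
        rec.global_tm = tm_score(fixed, moving).score
    for name, frame in config.resolved_region_frames().items():
        spec = regions[name]
        try:
            r, tm = region_metrics(native, pred, corr, spec, frame, config.cdr_windows)
        except EmptyRegionError:
            continue
        rec.region[name] = RegionResult(rmsd=r, tm=tm.score)
    for name in config.resolved_plddt_regions():
        try:
            rec.plddt[name] = region_plddt(pred, regions[name])
        except (ConfidenceError, EmptyRegionError):
            continue  # prediction without pLDDT: fields stay absent
    if bundle is not None:
        rec.ptm, rec.iptm = bundle.ptm, bundle.iptm
        rec.ranking_score = bundle.ranking_score
    return rec


def records_to_frame(records: List[EvaluationRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (TSV-ready, stable column order)."""
    rows = [r.to_row() for r in records]
    df = pd.DataFrame(rows)
    fixed_cols = [
        "complex_id", "candidate_id", "original_rank", "atom_mode",
        "fnat", "irms", "lrms", "dockq", "quality_class",
        "global_rmsd", "global_tm", "ptm", "iptm", "ranking_score",
    ]
    other = sorted(c for c in df.columns if c not in fixed_cols)
    return df[[c for c in fixed_cols if c in df.columns] + other]


def frame_to_records(df: pd.DataFrame) -> List[EvaluationRecord]:
    return [EvaluationRecord.from_row(row) for row in df.to_dict("records")]
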