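"""Parsing, validation and annotation of native / predicted complexes.

The central container is :class:`RoledComplex`: an ordered list of chains,
each carrying a role (TCR alpha/beta, peptide, MHC), its residues in file
order, optional per-residue pLDDT (read from the B-factor column of
prediction files, the folding-model convention) and optional IMGT numbers
supplied by an external numbering table.

All downstream metrics run on C-alpha coordinates; a residue without a
C-alpha atom is dropped at parse time.  Correspondence between a native
structure and a prediction is ordinal within each role and requires
identical sequences, so insertion codes and author numbering never enter
the metric math.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np
import pandas as pd

from ._errors import (
    CorrespondenceError,
    EmptyRegionError,
    FormatError,
    MappingError,
    NumberingError,
    RoleError,
)
from .regions import MANDATORY_ROLES, RegionSpec, Role

_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


@dataclass
class Residue:
    """One residue with its C-alpha coordinate and optional annotations."""

    chain_id: str
    author_seq_id: int
    icode: str
    position_index: int  # 0-based ordinal within the chain
    amino_acid: str  # 1-letter code, 'X' for hetero/modified
    ca: np.ndarray  # (3,) in Angstrom
    atoms: Tuple[Tuple[str, np.ndarray], ...] = ()
    plddt: Optional[float] = None
    imgt: Optional[int] = None

    @property
    def key(self) -> Tuple[str, int]:
        return (self.chain_id, self.position_index)

    def all_coords(self) -> np.ndarray:
        """All atom coordinates (falls back to the C-alpha alone)."""
        if self.atoms:
            return np.asarray([xyz for _, xyz in self.atoms], dtype=float)
        return self.ca[None, :]


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue]
    role: Optional[Role] = None

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.asarray([r.ca for r in self.residues], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RoledComplex:
    """A (possibly not yet role-annotated) TCR-pMHC complex."""

    chains: List[Chain]
    mhc_class: Optional[str] = None  # "I" or "II"
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def roles(self) -> Tuple[Role, ...]:
        return tuple(c.role for c in self.chains if c.role is not None)

    def chain(self, role: Role) -> Chain:
        for c in self.chains:
            if c.role == role:
                return c
        raise RoleError(f"no chain with role {role}")

    def has_role(self, role: Role) -> bool:
        return any(c.role == role for c in self.chains)

    def chain_by_id(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise MappingError(f"no chain with id {chain_id!r}")

    def residues(self, roles: Optional[Iterable[Role]] = None) -> Iterator[Residue]:
        wanted = None if roles is None else set(roles)
        for c in self.chains:
            if wanted is None or c.role in wanted:
                yield from c.residues

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def has_full_atoms(self) -> bool:
        """True when every residue carries more atoms than just the C-alpha."""
        return all(len(r.atoms) > 1 for c in self.chains for r in c.residues)


def autoscale_plddt(values: Sequence[float], context: str = "pLDDT") -> List[float]:
    """Normalise pLDDT to the 0-100 scale.

    Folding models emit pLDDT either on 0-1 or 0-100; if every value is
    <= 1.0 the list is multiplied by 100 (with a warning).  Values outside
    [0, 100] after scaling are an error.
    """
    vals = [float(v) for v in values]
    if vals and all(v <= 1.0 for v in vals):
        warnings.warn(f"{context}: all values <= 1.0, rescaling to 0-100")
        vals = [v * 100.0 for v in vals]
    for v in vals:
        if not (0.0 <= v <= 100.0):
            raise FormatError(f"{context}: value {v} outside [0, 100] after scaling")
    return vals


def read_structure(path: Union[str, Path], source: str = "native") -> RoledComplex:
    """Read a PDB file into a :class:`RoledComplex` with roles unassigned.

    Every residue with a C-alpha atom is retained in file order (hetero or
    modified residues become amino acid 'X'); waters and C-alpha-free
    ligands are dropped.  Alternate locations resolve to the first
    occurrence.  For ``source="prediction"`` the C-alpha B-factor column is
    captured as candidate pLDDT, with the 0-1 -> 0-100 auto-scale rule.
    """
    if source not in ("native", "prediction"):
        raise ValueError(f"source must be 'native' or 'prediction', got {source!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")

    chains: List[Chain] = []
    bvals: List[float] = []
    for gchain in st[0]:
        residues: List[Residue] = []
        for gres in gchain:
            if gres.is_water():
                continue
            ca = None
            for atom in gres:
                if atom.name == "CA" and ca is None:
                    ca = atom  # first occurrence wins over altlocs
            if ca is None:
                continue
            info = gemmi.find_tabulated_residue(gres.name)
            if info is not None and info.is_amino_acid():
                one = info.one_letter_code.upper()
                aa = one if one.isalpha() and one != " " else "X"
            else:
                aa = "X"
            atoms: List[Tuple[str, np.ndarray]] = []
            seen_names = set()
            for atom in gres:
                if atom.name in seen_names:  # first altloc only
                    continue
                seen_names.add(atom.name)
                atoms.append((atom.name, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    author_seq_id=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    position_index=len(residues),
                    amino_acid=aa,
                    ca=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                    atoms=tuple(atoms),
                )
            )
            bvals.append(float(ca.b_iso))
        if not residues:
            warnings.warn(f"{path}: chain {gchain.name!r} has no C-alpha residues, dropped")
            continue
        chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise FormatError(f"{path}: no chain with C-alpha atoms")

    if source == "prediction":
        scaled = autoscale_plddt(bvals, context=f"{path} B-factor pLDDT")
        it = iter(scaled)
        for c in chains:
            for r in c.residues:
                r.plddt = next(it)

    return RoledComplex(chains=chains, metadata={"path": str(path), "source": source})


def assign_roles(
    c: RoledComplex,
    role_map: Mapping[str, Union[Role, str]],
    mhc_class: str = "I",
) -> RoledComplex:
    """Attach chain roles in place and enforce the complex invariants.

    ``role_map`` maps chain id -> role and must cover every retained chain.
    Class I requires exactly TCRA, TCRB, PEPTIDE and MHC_A; class II
    additionally requires MHC_B.
    """
    if mhc_class not in ("I", "II"):
        raise RoleError(f"mhc_class must be 'I' or 'II', got {mhc_class!r}")
    present = {ch.chain_id for ch in c.chains}
    unknown = set(role_map) - present
    if unknown:
        raise MappingError(f"role map references absent chains: {sorted(unknown)}")
    missing = present - set(role_map)
    if missing:
        raise MappingError(f"role map does not cover chains: {sorted(missing)}")

    seen: Dict[Role, str] = {}
    for ch in c.chains:
        role = Role(role_map[ch.chain_id])
        if role in seen:
            raise RoleError(f"role {role} assigned to both {seen[role]!r} and {ch.chain_id!r}")
        seen[role] = ch.chain_id
        ch.role = role

    for role in MANDATORY_ROLES:
        if role not in seen:
            raise RoleError(f"mandatory role {role} missing")
    if mhc_class == "II" and Role.MHC_B not in seen:
        raise RoleError("class II complex requires an MHC_B chain")
    if mhc_class == "I" and Role.MHC_B in seen:
        raise RoleError("class I complex must not carry an MHC_B chain")
    c.mhc_class = mhc_class
    return c


def attach_numbering(
    c: RoledComplex, table: Union[pd.DataFrame, str, Path]
) -> RoledComplex:
    """Attach IMGT numbers to TCR residues from a numbering table.

    The table (TSV with header, or DataFrame) has columns ``chain_id``,
    ``author_seq_id``, ``imgt_number``.  Rows must reference existing
    residues; duplicates are an error.  Non-referenced residues keep no
    number; non-TCR chains are untouched.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype={"chain_id": str})
    required = {"chain_id", "author_seq_id", "imgt_number"}
    if not required.issubset(table.columns):
        raise NumberingError(f"numbering table needs columns {sorted(required)}")
    dup = table.duplicated(subset=["chain_id", "author_seq_id"])
    if dup.any():
        row = table[dup].iloc[0]
        raise NumberingError(
            f"duplicate numbering row for chain {row['chain_id']!r} "
            f"residue {row['author_seq_id']}"
        )
    index: Dict[Tuple[str, int], Residue] = {}
    for ch in c.chains:
        for r in ch.residues:
            index.setdefault((ch.chain_id, r.author_seq_id), r)
    for _, row in table.iterrows():
        key = (str(row["chain_id"]), int(row["author_seq_id"]))
        if key not in index:
            raise NumberingError(f"numbering row references absent residue {key}")
        index[key].imgt = int(row["imgt_number"])
    return c


def select_region(c: RoledComplex, spec: RegionSpec) -> List[Residue]:
    """Residues of ``c`` falling in any window of ``spec``, in chain order.

    IMGT windows use inclusive bounds; whole-chain windows return the chain.
    Windows whose role is absent from the complex (e.g. MHC_B on a class I
    complex) are skipped; an overall empty selection is an error, because
    callers average over the region.
    """
    out: List[Residue] = []
    for w in spec.windows:
        if not c.has_role(w.role):
            continue
        ch = c.chain(w.role)
        if w.whole_chain:
            out.extend(ch.residues)
        else:
            out.extend(
                r for r in ch.residues
                if r.imgt is not None and w.start <= r.imgt <= w.end  # type: ignore[operator]
            )
    if not out:
        raise EmptyRegionError(f"region {spec.name!r} selects no residues")
    return out


@dataclass
class CorrespondenceMap:
    """One-to-one native <-> prediction residue pairing, ordinal within role."""

    pairs: List[Tuple[Residue, Residue]]
    _by_native: Dict[Tuple[str, int], Residue] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_native:
            self._by_native = {nat.key: pred for nat, pred in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def pred_of(self, native_res: Residue) -> Residue:
        return self._by_native[native_res.key]

    def coords(
        self, native_subset: Optional[Sequence[Residue]] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """(native Nx3, predicted Nx3) C-alpha arrays for a residue subset."""
        if native_subset is None:
            nats = [nat for nat, _ in self.pairs]
        else:
            nats = list(native_subset)
        fixed = np.asarray([r.ca for r in nats], dtype=float)
        moving = np.asarray([self.pred_of(r).ca for r in nats], dtype=float)
        return fixed, moving


def pair_residues(native: RoledComplex, pred: RoledComplex) -> CorrespondenceMap:
    """Pair residues by ordinal position within each role.

    Requires the same role set and identical per-role sequences ('X'
    matches only 'X').  Pairing is by role, not file order.
    """
    nroles, proles = set(native.roles), set(pred.roles)
    if nroles != proles:
        raise CorrespondenceError(
            f"role sets differ: native {sorted(r.value for r in nroles)} "
            f"vs prediction {sorted(r.value for r in proles)}"
        )
    pairs: List[Tuple[Residue, Residue]] = []
    for role in [c.role for c in native.chains if c.role is not None]:
        nch, pch = native.chain(role), pred.chain(role)
        if len(nch) != len(pch):
            raise CorrespondenceError(
                f"{role}: length mismatch ({len(nch)} native vs {len(pch)} predicted)"
            )
        for i, (nr, pr) in enumerate(zip(nch.residues, pch.residues)):
            if nr.amino_acid != pr.amino_acid:
                raise CorrespondenceError(
                    f"{role}: sequence mismatch at position {i} "
                    f"({nr.amino_acid} vs {pr.amino_acid})"
                )
            pairs.append((nr, pr))
    return CorrespondenceMap(pairs=pairs)


def write_structure(c: RoledComplex, path: Union[str, Path]) -> None:
    """Write a complex as a PDB file (C-alpha plus any stored atoms).

    pLDDT, when present, is written to the B-factor column so the file
    round-trips through :func:`read_structure` with ``source="prediction"``.
    """
    st = gemmi.Structure()
    st.name = str(c.metadata.get("complex_id", "complex"))
    model = gemmi.Model("1")
    for ch in c.chains:
        gch = gemmi.Chain(ch.chain_id)
        for r in ch.residues:
            gres = gemmi.Residue()
            gres.name = _THREE_LETTER.get(r.amino_acid, "UNK")
            gres.seqid = gemmi.SeqId(r.author_seq_id, r.icode or " ")
            gres.het_flag = "A"
            b = float(r.plddt) if r.plddt is not None else 0.0
            atom_list = r.atoms if r.atoms else (("CA", r.ca),)
            for name, xyz in atom_list:
                a = gemmi.Atom()
                a.name = name
                a.pos = gemmi.Position(*[round(float(v), 3) for v in xyz])
                a.occ = 1.0
                a.b_iso = round(b, 2)
                a.element = gemmi.Element(name[:1] if name[:1] in "CNOSH" else "C")
                gres.add_atom(a)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    Path(path).write_text(st.make_pdb_string())
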