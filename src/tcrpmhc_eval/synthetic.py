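"""Seeded synthetic TCR-pMHC complexes, candidate predictions and
mutation tables.

The generator stands in for folding-model outputs so the whole evaluation
pipeline is testable without any folding model or download.  It emulates:

* **Natives** — C-alpha-only class-I-like (or class-II-like) complexes on
  idealised helical backbone traces (~3.8 A consecutive C-alpha spacing):
  an MHC groove built from two helical strands, the peptide lying between
  them, and the TCR body above with the two CDR3 loops (IMGT 105-117)
  arcing down to form the contact interface.  TCR chains come with an
  IMGT numbering table covering the CDR1/CDR2/CDR3 windows.
* **Candidates** — K predictions per complex produced by a rigid-body
  perturbation of the TCR relative to the pMHC (random rotation +
  translation), a CDR3-local distortion whose amplitude grows with the
  rigid displacement (so loop error co-varies with docking error, as it
  does for real predictors), and i.i.d. Gaussian jitter on every residue.
  Per-residue pLDDT couples to the residue's true displacement e_i via

      plddt_i = clip(100 * exp(-e_i / 2) * c + 100 * u_i * (1 - c), 0, 100)

  with coupling c = ``c_plddt`` and u_i ~ Uniform(0, 1); the ranking score
  is built analogously from the interface error with coupling ``c_rank``.
* **Mutation pairs** — ddG values with a planted probability that the
  CDR3 pLDDT change opposes the ddG sign (concordance), at sites drawn
  from the CDR3 key positions (IMGT 109-113).

Identical config + seed give identical outputs, file-for-file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .confidence import ConfidenceBundle
from .dockq import PMHC_SPLIT, TCR_PMHC_SPLIT, interface_contacts
from .regions import CDR3_KEY_POSITIONS, DEFAULT_CDR_WINDOWS, Role
from .structures import (
    Chain,
    Residue,
    RoledComplex,
    attach_numbering,
    write_structure,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CHAIN_IDS = {Role.TCRA: "D", Role.TCRB: "E", Role.PEPTIDE: "C",
              Role.MHC_A: "A", Role.MHC_B: "B"}

# ideal alpha-helical C-alpha trace parameters: 2.3 A radius, 1.5 A rise,
# 100 degrees per residue -> 3.83 A consecutive spacing
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort."""

    seed: int = 0
    sizes: Dict[Role, int] = field(default_factory=lambda: {
        Role.TCRA: 50, Role.TCRB: 50, Role.PEPTIDE: 9,
        Role.MHC_A: 60, Role.MHC_B: 60,
    })
    mhc_class: str = "I"
    k_candidates: int = 5
    rotation_range: Tuple[float, float] = (0.0, 15.0)  # degrees
    translation_range: Tuple[float, float] = (0.0, 10.0)  # Angstrom
    jitter_sigma: float = 0.25  # Angstrom, per-residue
    cdr3_distortion: float = 0.4  # CDR3-local error per Angstrom of rigid shift
    c_plddt: float = 0.9
    c_rank: float = 0.5
    # mutation plant
    n_pairs: int = 81
    p_concordant: float = 0.753
    tie_rate: float = 0.05
    p_negative_ddg: float = 17.0 / 81.0
    ddg_range: Tuple[float, float] = (0.2, 2.5)  # kcal/mol

    def validate(self) -> None:
        for lo, hi in (self.rotation_range, self.translation_range):
            if lo < 0 or hi < lo:
                raise ConfigError("perturbation ranges must be non-negative and ordered")
        for name in ("jitter_sigma", "cdr3_distortion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("c_plddt", "c_rank", "p_concordant", "tie_rate", "p_negative_ddg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.k_candidates < 1:
            raise ConfigError("k_candidates must be >= 1")
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        for role, n in self.sizes.items():
            if n < 5:
                raise ConfigError(f"{role}: at least 5 residues needed to form an interface")
        if self.sizes[Role.TCRA] < 13 or self.sizes[Role.TCRB] < 13:
            raise ConfigError("TCR chains need >= 13 residues for the CDR3 loop")


def _helix(n: int, origin: np.ndarray, direction: np.ndarray, phase: float = 0.0) -> np.ndarray:
    """n C-alpha points on an ideal helix along ``direction`` from ``origin``."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame around the axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(direction[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    i = np.arange(n)
    ang = phase + i * _HELIX_TURN
    return (
        np.asarray(origin, dtype=float)
        + np.outer(i * _HELIX_RISE, direction)
        + _HELIX_RADIUS * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )


def _cdr3_arc(n: int, y: float, top_z: float = 12.5, bottom_z: float = 5.3) -> np.ndarray:
    """n points on a circular arc in an x-z plane dipping from top_z to bottom_z."""
    depth = top_z - bottom_z
    # fixed arc angle; radius solved from the sagitta: depth = R*(1 - cos(theta/2)),
    # which at these defaults gives ~3.8 A chord spacing for a 13-residue loop
    theta = 1.3
    radius = depth / (1.0 - np.cos(theta / 2.0))
    phi = np.linspace(-theta / 2.0, theta / 2.0, n)
    x = radius * np.sin(phi)
    z = (bottom_z + radius) - radius * np.cos(phi)
    return np.column_stack([x, np.full(n, y), z])


def _tcr_numbering(n: int) -> List[int]:
    """IMGT numbers for an n-residue TCR chain, centred on CDR3 105-117.

    For n >= 41 the chain also covers the CDR1 (27-38) and CDR2 (56-65)
    windows with framework residues in between; shorter chains get a
    consecutive numbering that guarantees only the CDR3 window.
    """
    if n < 41:
        pre = (n - 13) // 2
        start = 105 - pre
        return list(range(start, start + n))
    nums: List[int] = []
    blocks = [(27, 38), (56, 65), (105, 117)]  # CDR1, CDR2, CDR3
    extra = n - sum(hi - lo + 1 for lo, hi in blocks)  # framework residues
    fw_sizes = [extra // 4 + (1 if i < extra % 4 else 0) for i in range(4)]
    # before CDR1 / between CDR1-CDR2 / between CDR2-CDR3 / after CDR3
    nums += list(range(27 - fw_sizes[0], 27))
    nums += list(range(27, 39))
    nums += list(range(39, 39 + fw_sizes[1]))
    nums += list(range(56, 66))
    nums += list(range(66, 66 + fw_sizes[2]))
    nums += list(range(105, 118))
    nums += list(range(118, 118 + fw_sizes[3]))
    return nums


def _make_chain(role: Role, coords: np.ndarray, seq: str) -> Chain:
    cid = _CHAIN_IDS[role]
    residues = [
        Residue(chain_id=cid, author_seq_id=i + 1, icode="", position_index=i,
                amino_acid=seq[i], ca=coords[i].copy())
        for i in range(len(coords))
    ]
    return Chain(chain_id=cid, residues=residues, role=role)


def make_native(
    cfg: GeneratorConfig,
    complex_id: str = "synth_0000",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[RoledComplex, pd.DataFrame]:
    """Build one native complex and its TCR IMGT numbering table."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sizes = cfg.sizes
    chains: List[Chain] = []

    def seq(n: int) -> str:
        return "".join(rng.choice(list(_AA), size=n))

    # --- pMHC platform ---------------------------------------------------
    n_pep = sizes[Role.PEPTIDE]
    pep = _helix(n_pep, origin=np.array([-(n_pep - 1) * _HELIX_RISE / 2.0, 0.0, 0.0]),
                 direction=np.array([1.0, 0.0, 0.0]))
    if cfg.mhc_class == "I":
        n_mhc = sizes[Role.MHC_A]
        half = n_mhc // 2
        s1 = _helix(half, origin=np.array([-(half - 1) * _HELIX_RISE / 2.0, 8.0, -3.0]),
                    direction=np.array([1.0, 0.0, 0.0]))
        s2 = _helix(n_mhc - half,
                    origin=np.array([(n_mhc - half - 1) * _HELIX_RISE / 2.0, -8.0, -3.0]),
                    direction=np.array([-1.0, 0.0, 0.0]))
        mhc_chains = [(Role.MHC_A, np.vstack([s1, s2]))]
    else:
        n_a, n_b = sizes[Role.MHC_A], sizes[Role.MHC_B]
        sa = _helix(n_a, origin=np.array([-(n_a - 1) * _HELIX_RISE / 2.0, 8.0, -3.0]),
                    direction=np.array([1.0, 0.0, 0.0]))
        sb = _helix(n_b, origin=np.array([(n_b - 1) * _HELIX_RISE / 2.0, -8.0, -3.0]),
                    direction=np.array([-1.0, 0.0, 0.0]))
        mhc_chains = [(Role.MHC_A, sa), (Role.MHC_B, sb)]

    # --- TCR body with CDR3 loops arcing down to the peptide -------------
    def tcr_coords(n: int, y_fw: float, y_cdr3: float) -> Tuple[np.ndarray, List[int]]:
        nums = _tcr_numbering(n)
        lo, hi = DEFAULT_CDR_WINDOWS["CDR3"]
        is_cdr3 = [lo <= m <= hi for m in nums]
        n_fw = n - sum(is_cdr3)
        fw = _helix(n_fw, origin=np.array([-(n_fw - 1) * _HELIX_RISE / 2.0, y_fw, 13.5]),
                    direction=np.array([1.0, 0.0, 0.0]))
        arc = _cdr3_arc(sum(is_cdr3), y=y_cdr3)
        coords = np.empty((n, 3))
        i_fw = i_arc = 0
        for i, flag in enumerate(is_cdr3):
            if flag:
                coords[i] = arc[i_arc]
                i_arc += 1
            else:
                coords[i] = fw[i_fw]
                i_fw += 1
        return coords, nums

    ca_coords, ca_nums = tcr_coords(sizes[Role.TCRA], y_fw=-6.0, y_cdr3=-3.5)
    cb_coords, cb_nums = tcr_coords(sizes[Role.TCRB], y_fw=6.0, y_cdr3=3.5)

    # tiny seeded jitter breaks exact symmetries without moving the interface
    def jitter(x: np.ndarray) -> np.ndarray:
        return x + rng.normal(0.0, 0.05, size=x.shape)

    chains.append(_make_chain(Role.TCRA, jitter(ca_coords), seq(sizes[Role.TCRA])))
    chains.append(_make_chain(Role.TCRB, jitter(cb_coords), seq(sizes[Role.TCRB])))
    chains.append(_make_chain(Role.PEPTIDE, jitter(pep), seq(n_pep)))
    for role, coords in mhc_chains:
        chains.append(_make_chain(role, jitter(coords), seq(len(coords))))

    native = RoledComplex(chains=chains, mhc_class=cfg.mhc_class,
                          metadata={"complex_id": complex_id, "source": "native"})

    numbering_rows = []
    for cid, nums in ((_CHAIN_IDS[Role.TCRA], ca_nums), (_CHAIN_IDS[Role.TCRB], cb_nums)):
        for i, m in enumerate(nums):
            numbering_rows.append({"chain_id": cid, "author_seq_id": i + 1, "imgt_number": m})
    numbering = pd.DataFrame(numbering_rows)
    attach_numbering(native, numbering)

    tcr_contacts = interface_contacts(native, TCR_PMHC_SPLIT, atom_mode="ca")
    pmhc_contacts = interface_contacts(native, PMHC_SPLIT, atom_mode="ca")
    if len(tcr_contacts) < 10 or len(pmhc_contacts) < 3:
        raise ConfigError(
            f"sizes too small to form an interface "
            f"({len(tcr_contacts)} TCR-pMHC, {len(pmhc_contacts)} peptide-MHC contacts)"
        )
    return native, numbering


@dataclass
class Candidate:
    """One synthetic prediction with its confidence metadata."""

    candidate_id: str
    structure: RoledComplex
    bundle: ConfidenceBundle
    original_rank: int
    rigid_translation: float  # magnitude drawn, for diagnostics


def _random_rotation(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _copy_complex(c: RoledComplex) -> RoledComplex:
    chains = []
    for ch in c.chains:
        residues = [replace(r, ca=r.ca.copy(), atoms=tuple()) for r in ch.residues]
        chains.append(Chain(chain_id=ch.chain_id, residues=residues, role=ch.role))
    return RoledComplex(chains=chains, mhc_class=c.mhc_class, metadata=dict(c.metadata))


def make_candidates(
    native: RoledComplex,
    cfg: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Candidate]:
    """K perturbed predictions of a native with coupled confidence scores."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    lo_a, hi_a = cfg.rotation_range
    lo_t, hi_t = cfg.translation_range
    cdr_lo, cdr_hi = DEFAULT_CDR_WINDOWS["CDR3"]

    from .dockq import native_interface_residues

    iface_keys = {r.key for r in native_interface_residues(native, TCR_PMHC_SPLIT)}

    drafts = []
    for k in range(cfg.k_candidates):
        pred = _copy_complex(native)
        pred.metadata["source"] = "prediction"
        angle = rng.uniform(lo_a, hi_a)
        tmag = rng.uniform(lo_t, hi_t)
        tdir = rng.normal(size=3)
        tdir /= np.linalg.norm(tdir)
        rot = _random_rotation(rng, angle)
        tcr_res = [r for r in pred.residues((Role.TCRA, Role.TCRB))]
        centroid = np.mean([r.ca for r in tcr_res], axis=0)

        # CDR3-local distortion scales with the rigid displacement magnitude
        amp = cfg.cdr3_distortion * tmag
        for role in (Role.TCRA, Role.TCRB):
            loop_dir = rng.normal(size=3)
            loop_dir /= np.linalg.norm(loop_dir)
            for r in pred.chain(role).residues:
                if r.imgt is not None and cdr_lo <= r.imgt <= cdr_hi:
                    r.ca = r.ca + amp * loop_dir + rng.normal(0.0, amp / 2.0 + 1e-12, size=3)
        # rigid motion of the whole TCR body about its centroid
        for r in tcr_res:
            r.ca = rot @ (r.ca - centroid) + centroid + tmag * tdir
        # i.i.d. jitter everywhere
        for r in pred.residues():
            r.ca = r.ca + rng.normal(0.0, cfg.jitter_sigma, size=3)

        # per-residue true displacement drives pLDDT
        errors = {}
        for nat, prd in zip(native.residues(), pred.residues()):
            errors[nat.key] = float(np.linalg.norm(prd.ca - nat.ca))
        plddt_map: Dict[Tuple[str, int], float] = {}
        for r in pred.residues():
            e = errors[r.key]
            u = rng.uniform()
            val = 100.0 * np.exp(-e / 2.0) * cfg.c_plddt + 100.0 * u * (1.0 - cfg.c_plddt)
            val = float(np.clip(val, 0.0, 100.0))
            r.plddt = val
            plddt_map[r.key] = val

        iface_err = float(np.sqrt(np.mean([errors[k_] ** 2 for k_ in iface_keys])))
        rank_score = cfg.c_rank * np.exp(-iface_err / 5.0) + (1 - cfg.c_rank) * rng.uniform()
        mean_plddt = float(np.mean(list(plddt_map.values())))
        bundle = ConfidenceBundle(
            per_residue_plddt=plddt_map,
            ptm=float(np.clip(np.exp(-iface_err / 8.0) + rng.normal(0, 0.02), 0, 1)),
            iptm=float(np.clip(np.exp(-iface_err / 6.0) + rng.normal(0, 0.03), 0, 1)),
            ranking_score=float(rank_score),
            source="json",
        )
        pred.metadata["mean_plddt"] = mean_plddt
        drafts.append((rank_score, k, pred, bundle, tmag))

    out: List[Candidate] = []
    order = sorted(range(len(drafts)), key=lambda i: (-drafts[i][0], i))
    for rank, i in enumerate(order, start=1):
        _, k, pred, bundle, tmag = drafts[i]
        cid = f"cand_{rank}"
        pred.metadata["candidate_id"] = cid
        out.append(Candidate(candidate_id=cid, structure=pred, bundle=bundle,
                             original_rank=rank, rigid_translation=tmag))
    return out


def make_mutation_pairs(
    cfg: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    dataset: str = "synthetic",
) -> pd.DataFrame:
    """Mutation table with planted concordance structure.

    Each row is a single-point CDR3 mutation (site uniform over the IMGT
    key positions 109-113) with a ddG drawn from +/- the magnitude range.
    With probability ``p_concordant`` the planted CDR3-pLDDT change
    opposes the ddG sign; otherwise it matches the sign or, at
    ``tie_rate``, is exactly zero.  Weakly informative ipTM and ranking
    score changes are planted alongside for comparison.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    lo, hi = cfg.ddg_range
    pos_lo, pos_hi = CDR3_KEY_POSITIONS
    rows = []
    for i in range(cfg.n_pairs):
        sign = -1.0 if rng.uniform() < cfg.p_negative_ddg else 1.0
        ddg = sign * rng.uniform(lo, hi)
        wt_aa, mut_aa = rng.choice(list(_AA), size=2, replace=False)

        def planted_delta(p_conc: float) -> float:
            mag = rng.uniform(0.2, 4.0)
            if rng.uniform() < p_conc:
                return -np.sign(ddg) * mag
            if rng.uniform() < cfg.tie_rate:
                return 0.0
            return np.sign(ddg) * mag

        d_plddt = planted_delta(cfg.p_concordant)
        d_iptm = planted_delta(0.55) / 100.0
        d_rank = planted_delta(0.55) / 100.0
        wt_plddt = rng.uniform(70.0, 95.0)
        wt_iptm = rng.uniform(0.6, 0.9)
        wt_rank = rng.uniform(0.6, 0.9)
        rows.append({
            "pair_id": f"mut_{i:04d}",
            "complex_id": f"synth_{i % 5:04d}",
            "chain": rng.choice(["A", "B"]),
            "imgt_position": int(rng.integers(pos_lo, pos_hi + 1)),
            "wt_aa": wt_aa, "mut_aa": mut_aa,
            "ddg": round(float(ddg), 4),
            "dataset": dataset,
            "wt_CDR3_pLDDT": round(float(wt_plddt), 4),
            "mut_CDR3_pLDDT": round(float(wt_plddt + d_plddt), 4),
            "wt_iptm": round(float(wt_iptm), 4),
            "mut_iptm": round(float(np.clip(wt_iptm + d_iptm, 0, 1)), 4),
            "wt_ranking_score": round(float(wt_rank), 4),
            "mut_ranking_score": round(float(np.clip(wt_rank + d_rank, 0, 1)), 4),
        })
    return pd.DataFrame(rows)


def write_confidence_json(bundle: ConfidenceBundle, c: RoledComplex, path: Union[str, Path]) -> None:
    """Write a candidate's confidence bundle as the JSON sidecar schema."""
    plddt: Dict[str, List[float]] = {}
    for ch in c.chains:
        plddt[ch.chain_id] = [
            round(bundle.per_residue_plddt[(ch.chain_id, r.position_index)], 2)
            for r in ch.residues
        ]
    data = {
        "plddt": plddt,
        "ptm": None if bundle.ptm is None else round(bundle.ptm, 4),
        "iptm": None if bundle.iptm is None else round(bundle.iptm, 4),
        "ranking_score": None if bundle.ranking_score is None else round(bundle.ranking_score, 4),
    }
    Path(path).write_text(json.dumps(data, indent=1))


def write_cohort(
    cfg: GeneratorConfig,
    n_complexes: int,
    out_dir: Union[str, Path],
) -> pd.DataFrame:
    """Generate a cohort on disk: PDBs, confidence JSONs, tables, manifest.

    Layout: ``<out_dir>/<complex_id>/{native.pdb, role_map.tsv,
    numbering.tsv, cand_k.pdb, cand_k.confidence.json}`` plus a root
    ``manifest.tsv``.  Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest_rows = []
    for i in range(n_complexes):
        complex_id = f"synth_{i:04d}"
        cdir = out_dir / complex_id
        cdir.mkdir(exist_ok=True)
        native, numbering = make_native(cfg, complex_id=complex_id, rng=rng)
        write_structure(native, cdir / "native.pdb")
        numbering.to_csv(cdir / "numbering.tsv", sep="\t", index=False)
        role_rows = [{"chain_id": ch.chain_id, "role": ch.role.value} for ch in native.chains]
        pd.DataFrame(role_rows).to_csv(cdir / "role_map.tsv", sep="\t", index=False)
        for cand in make_candidates(native, cfg, rng=rng):
            pdb_path = cdir / f"{cand.candidate_id}.pdb"
            conf_path = cdir / f"{cand.candidate_id}.confidence.json"
            write_structure(cand.structure, pdb_path)
            write_confidence_json(cand.bundle, cand.structure, conf_path)
            # paths relative to the manifest so the cohort is relocatable
            manifest_rows.append({
                "complex_id": complex_id,
                "candidate_id": cand.candidate_id,
                "native": f"{complex_id}/native.pdb",
                "prediction": f"{complex_id}/{cand.candidate_id}.pdb",
                "confidence": f"{complex_id}/{cand.candidate_id}.confidence.json",
                "original_rank": cand.original_rank,
                "role_map": f"{complex_id}/role_map.tsv",
                "numbering": f"{complex_id}/numbering.tsv",
                "mhc_class": cfg.mhc_class,
            })
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
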