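"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's own superposition and
contact code: plain double loops, scipy's Rotation.align_vectors, and a
random-rotation search with local refinement.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def aligned_rmsd_oracle(fixed: np.ndarray, moving: np.ndarray) -> float:
    """Superposed RMSD via scipy's independent Kabsch (align_vectors)."""
    f0 = fixed - fixed.mean(axis=0)
    m0 = moving - moving.mean(axis=0)
    _, rssd = Rotation.align_vectors(f0, m0)
    return float(rssd / np.sqrt(len(fixed)))


def brute_rotation_rmsd(fixed: np.ndarray, moving: np.ndarray,
                        n_samples: int = 2000, seed: int = 0) -> float:
    """Superposed RMSD by random proper-rotation search + local refinement."""
    f0 = fixed - fixed.mean(axis=0)
    m0 = moving - moving.mean(axis=0)

    def cost_rot(r: Rotation) -> float:
        return float(np.sqrt(np.mean(np.sum((r.apply(m0) - f0) ** 2, axis=1))))

    rots = Rotation.random(n_samples, rng=np.random.default_rng(seed))
    costs = [cost_rot(r) for r in rots]
    best = rots[int(np.argmin(costs))]

    def cost_vec(v: np.ndarray) -> float:
        return cost_rot(Rotation.from_rotvec(v))

    res = minimize(cost_vec, best.as_rotvec(), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


def residue_min_distance(res_a, res_b, atom_mode: str) -> float:
    if atom_mode == "ca":
        return float(np.linalg.norm(res_a.ca - res_b.ca))
    best = np.inf
    for _, xa in (res_a.atoms or (("CA", res_a.ca),)):
        for _, xb in (res_b.atoms or (("CA", res_b.ca),)):
            best = min(best, float(np.linalg.norm(np.asarray(xa) - np.asarray(xb))))
    return best


def brute_contacts(complex_, receptor_roles, ligand_roles, atom_mode, cutoff):
    """All cross-body contacts by exhaustive pair enumeration."""
    rec = [r for c in complex_.chains if c.role in receptor_roles for r in c.residues]
    lig = [r for c in complex_.chains if c.role in ligand_roles for r in c.residues]
    out = set()
    for ra, rb in itertools.product(rec, lig):
        if residue_min_distance(ra, rb, atom_mode) < cutoff:
            out.add((ra.key, rb.key))
    return out


def brute_fnat(native, pred, receptor_roles, ligand_roles, atom_mode, cutoff):
    native_contacts = brute_contacts(native, receptor_roles, ligand_roles, atom_mode, cutoff)
    pred_index = {}
    for nc, pc in zip(native.chains, pred.chains):
        by_role = {c.role: c for c in pred.chains}
        for nr, pr in zip(nc.residues, by_role[nc.role].residues):
            pred_index[nr.key] = pr
    kept = sum(
        1 for ka, kb in native_contacts
        if residue_min_distance(pred_index[ka], pred_index[kb], atom_mode) < cutoff
    )
    return kept / len(native_contacts)


def brute_interface_keys(native, receptor_roles, ligand_roles, atom_mode="ca", cutoff=10.0):
    keys = set()
    rec = [r for c in native.chains if c.role in receptor_roles for r in c.residues]
    lig = [r for c in native.chains if c.role in ligand_roles for r in c.residues]
    for ra, rb in itertools.product(rec, lig):
        if residue_min_distance(ra, rb, atom_mode) < cutoff:
            keys.add(ra.key)
            keys.add(rb.key)
    return keys


def brute_irms(native, pred, receptor_roles, ligand_roles, atom_mode="ca"):
    keys = brute_interface_keys(native, receptor_roles, ligand_roles, atom_mode)
    by_role = {c.role: c for c in pred.chains}
    fixed, moving = [], []
    for nc in native.chains:
        for nr, pr in zip(nc.residues, by_role[nc.role].residues):
            if nr.key in keys:
                fixed.append(nr.ca)
                moving.append(pr.ca)
    return aligned_rmsd_oracle(np.asarray(fixed), np.asarray(moving))


def brute_lrms(native, pred, receptor_roles, ligand_roles):
    by_role = {c.role: c for c in pred.chains}
    rec_f, rec_m, lig_f, lig_m = [], [], [], []
    for nc in native.chains:
        tgt_f, tgt_m = (rec_f, rec_m) if nc.role in receptor_roles else (lig_f, lig_m)
        for nr, pr in zip(nc.residues, by_role[nc.role].residues):
            tgt_f.append(nr.ca)
            tgt_m.append(pr.ca)
    rec_f, rec_m = np.asarray(rec_f), np.asarray(rec_m)
    lig_f, lig_m = np.asarray(lig_f), np.asarray(lig_m)
    fc, mc = rec_f.mean(axis=0), rec_m.mean(axis=0)
    rot, _ = Rotation.align_vectors(rec_f - fc, rec_m - mc)
    lig_m_fit = rot.apply(lig_m - mc) + fc
    return float(np.sqrt(np.mean(np.sum((lig_m_fit - lig_f) ** 2, axis=1))))


def dockq_formula(fnat, lrms, irms):
    return (fnat + 1 / (1 + (irms / 1.5) ** 2) + 1 / (1 + (lrms / 8.5) ** 2)) / 3
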