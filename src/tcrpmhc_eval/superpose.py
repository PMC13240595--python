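"""Kabsch superposition, RMSD and TM-score on C-alpha coordinates.

RMSD is the root-mean-square paired C-alpha distance, optionally after the
closed-form least-squares rigid superposition (Kabsch); reflections are
excluded by forcing det(R) = +1.

TM-score is the length-normalised similarity

    TM = (1 / L_N) * sum_i 1 / (1 + (d_i / d0)^2),
    d0 = 1.24 * (L_N - 15)^(1/3) - 1.8   (floored at 0.5 A),

maximised over superpositions found by an iterative refinement at fixed
residue correspondence: seed with Kabsch on all pairs, then for each
distance cutoff in {d0, 2 d0, 4 d0, 8 d0} repeatedly re-fit on the pairs
closer than the cutoff until the kept set is stable (max 20 iterations),
scoring all residues each round and keeping the best score seen.  The
correspondence is fixed because native and prediction share a sequence, so
no alignment search is needed.

Region metrics support three frames: ``local`` (superpose on the region
itself), ``framework`` (CDR regions only: superpose on the containing TCR
chains' non-CDR residues, then measure the loop without re-fitting) and
``global`` (superpose on all C-alpha).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np

from ._errors import GeometryError, ShapeError, TcrEvalError
from .regions import DEFAULT_CDR_WINDOWS, RegionSpec, Role, TCR_ROLES, Window
from .structures import CorrespondenceMap, RoledComplex, select_region

_TM_CUTOFF_FACTORS = (1.0, 2.0, 4.0, 8.0)
_TM_MAX_ITER = 20


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform: x_fit = R @ x_moving + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    fitted_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class TmScoreResult:
    score: float
    d0: float
    normalization_length: int


def _check_pair_shapes(fixed: np.ndarray, moving: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.ndim != 2 or fixed.shape[1] != 3 or moving.ndim != 2 or moving.shape[1] != 3:
        raise ShapeError("coordinates must be (N, 3) arrays")
    if fixed.shape[0] != moving.shape[0]:
        raise ShapeError(f"length mismatch: {fixed.shape[0]} vs {moving.shape[0]}")
    return fixed, moving


def kabsch(fixed: np.ndarray, moving: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation + translation (moving -> fixed)."""
    fixed, moving = _check_pair_shapes(fixed, moving)
    n = fixed.shape[0]
    if n < 3:
        raise GeometryError(f"kabsch needs >= 3 points, got {n}")
    fc, mc = fixed.mean(axis=0), moving.mean(axis=0)
    f0, m0 = fixed - fc, moving - mc
    # collinear point sets leave a rotation degree of freedom undetermined
    for label, arr in (("fixed", f0), ("moving", m0)):
        s = np.linalg.svd(arr, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise GeometryError(f"{label} points are (near-)collinear; superposition is degenerate")
    h = m0.T @ f0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = fc - rot @ mc
    fitted = float(np.sqrt(np.mean(np.sum((m0 @ rot.T - f0) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, fitted_rmsd=fitted)


def rmsd(fixed: np.ndarray, moving: np.ndarray, superpose: bool = True) -> float:
    """Root-mean-square paired distance, after Kabsch when ``superpose``."""
    fixed, moving = _check_pair_shapes(fixed, moving)
    if fixed.shape[0] < 1:
        raise ShapeError("rmsd needs at least one point")
    if superpose:
        return kabsch(fixed, moving).fitted_rmsd
    return float(np.sqrt(np.mean(np.sum((fixed - moving) ** 2, axis=1))))


def tm_d0(normalization_length: int) -> float:
    """TM-score distance scale with the 0.5 A floor for short lengths."""
    return max(0.5, 1.24 * np.cbrt(normalization_length - 15.0) - 1.8)


def tm_from_distances(d: np.ndarray, d0: float, normalization_length: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / normalization_length)


def tm_score(
    fixed: np.ndarray,
    moving: np.ndarray,
    normalization_length: Optional[int] = None,
) -> TmScoreResult:
    """TM-score at fixed correspondence, maximised by iterative refinement."""
    fixed, moving = _check_pair_shapes(fixed, moving)
    n = fixed.shape[0]
    if n < 3:
        raise GeometryError(f"tm_score needs >= 3 points, got {n}")
    ln = n if normalization_length is None else int(normalization_length)
    if ln < n:
        raise ShapeError(f"normalization_length {ln} < number of residues {n}")
    d0 = tm_d0(ln)

    def score_with(sup: Superposition) -> Tuple[float, np.ndarray]:
        d = np.linalg.norm(sup.apply(moving) - fixed, axis=1)
        return tm_from_distances(d, d0, ln), d

    sup = kabsch(fixed, moving)
    best, dists = score_with(sup)
    for factor in _TM_CUTOFF_FACTORS:
        cutoff = factor * d0
        keep = dists < cutoff
        prev: Optional[np.ndarray] = None
        for _ in range(_TM_MAX_ITER):
            if keep.sum() < 3:
                break
            if prev is not None and np.array_equal(keep, prev):
                break
            prev = keep.copy()
            try:
                sub = kabsch(fixed[keep], moving[keep])
            except GeometryError:
                break
            score, d_all = score_with(sub)
            best = max(best, score)
            keep = d_all < cutoff
    return TmScoreResult(score=best, d0=d0, normalization_length=ln)


def _framework_residues(
    native: RoledComplex,
    spec: RegionSpec,
    cdr_windows: Mapping[str, Tuple[int, int]],
):
    """Non-CDR residues of the TCR chains the CDR spec lives on."""
    roles = spec.roles
    if any(r not in TCR_ROLES for r in roles) or not spec.is_cdr:
        raise TcrEvalError(
            f"framework frame only applies to CDR regions on TCR chains, got {spec.name!r}"
        )
    windows = list(cdr_windows.values())
    out = []
    for role in roles:
        for r in native.chain(role).residues:
            in_cdr = r.imgt is not None and any(lo <= r.imgt <= hi for lo, hi in windows)
            if not in_cdr:
                out.append(r)
    return out


def region_metrics(
    native: RoledComplex,
    pred: RoledComplex,
    corr: CorrespondenceMap,
    spec: RegionSpec,
    frame: str = "local",
    cdr_windows: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> Tuple[float, TmScoreResult]:
    """(RMSD, TM-score) of a region under the requested superposition frame."""
    if frame not in ("local", "framework", "global"):
        raise ValueError(f"unknown frame {frame!r}")
    region = select_region(native, spec)
    fixed, moving = corr.coords(region)
    n = len(region)
    if frame == "local":
        r = rmsd(fixed, moving, superpose=True)
        tm = tm_score(fixed, moving, normalization_length=n)
        return r, tm
    if frame == "framework":
        fw = _framework_residues(native, spec, cdr_windows or DEFAULT_CDR_WINDOWS)
        if len(fw) < 3:
            raise GeometryError(f"fewer than 3 framework residues for {spec.name!r}")
        fw_fixed, fw_moving = corr.coords(fw)
        sup = kabsch(fw_fixed, fw_moving)
    else:  # global
        all_fixed, all_moving = corr.coords()
        sup = kabsch(all_fixed, all_moving)
    d = np.linalg.norm(sup.apply(moving) - fixed, axis=1)
    r = float(np.sqrt(np.mean(d**2)))
    d0 = tm_d0(n)
    tm = TmScoreResult(score=tm_from_distances(d, d0, n), d0=d0, normalization_length=n)
    return r, tm
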