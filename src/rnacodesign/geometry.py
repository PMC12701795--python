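"""Rigid-body superposition and structural similarity metrics.

Kabsch superposition (SVD with determinant correction, so reflections are
never returned), aligned RMSD over bead clouds, superposition-free lDDT, and
a TM-score variant with the nucleic-acid length normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["Superposition", "kabsch_align", "aligned_rmsd", "lddt", "tm_score"]


@dataclass
class Superposition:
    """A proper rigid motion (rotation then translation) and the RMSD it
    achieves.  ``rotation`` is orthonormal with det +1 within 1e-6."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _as_points(x) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim == 3:  # (L, beads, 3) -> flatten to a point cloud
        pts = pts.reshape(-1, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) point set, got shape {pts.shape}")
    return pts


def kabsch_align(mobile, reference) -> tuple[Superposition, np.ndarray]:
    """Optimal superposition of ``mobile`` onto ``reference``.

    Returns the :class:`Superposition` minimizing RMSD over all proper
    rotations and translations, and the transformed mobile points.
    Reflections are excluded by flipping the sign of the smallest singular
    vector when ``det < 0``.  Degenerate clouds (collinear, coincident) are
    handled by the same determinant-corrected SVD (singular-value tolerance
    1e-9 is implicit in LAPACK's thresholds).
    """
    mob = _as_points(mobile)
    ref = _as_points(reference)
    if mob.shape != ref.shape:
        raise ValueError(f"point count mismatch: {mob.shape} vs {ref.shape}")
    if mob.shape[0] == 0:
        raise ValueError("empty point sets")
    if not (np.all(np.isfinite(mob)) and np.all(np.isfinite(ref))):
        raise ValueError("non-finite coordinates")

    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    h = (mob - mob_c).T @ (ref - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    aligned = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1))))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd), aligned


def aligned_rmsd(a, b) -> float:
    """Kabsch RMSD between two bead arrays, flattened to L*3 points each."""
    pa, pb = _as_points(a), _as_points(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    sup, _ = kabsch_align(pa, pb)
    return sup.rmsd


DEFAULT_LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


def lddt(pred, ref, inclusion_radius: float = 15.0,
         thresholds=DEFAULT_LDDT_THRESHOLDS) -> float:
    """Superposition-free local distance difference test.

    Both arguments are bead arrays of equal shape, either ``(N, 3)`` or
    ``(L, 3, 3)``; in the latter case all three beads per residue enter and
    pairs of beads from the same residue are excluded.  Over all reference
    bead pairs closer than ``inclusion_radius``, the score is the fraction of
    pairs whose |d_pred - d_ref| falls under each threshold, averaged over
    the thresholds.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    if p.ndim == 3:
        residue_index = np.repeat(np.arange(p.shape[0]), p.shape[1])
    else:
        residue_index = np.arange(p.reshape(-1, 3).shape[0])
    p = p.reshape(-1, 3)
    r = r.reshape(-1, 3)
    n = p.shape[0]
    if n < 2:
        raise ValueError("lddt needs at least two beads")

    dr = cdist(r, r)
    dp = cdist(p, p)
    iu = np.triu_indices(n, k=1)
    same_residue = residue_index[iu[0]] == residue_index[iu[1]]
    included = (dr[iu] <= inclusion_radius) & ~same_residue
    if not np.any(included):
        raise ValueError("no reference pairs inside the inclusion radius")
    diff = np.abs(dp[iu][included] - dr[iu][included])
    fractions = [(diff < thr).mean() for thr in thresholds]
    return float(np.mean(fractions))


def tm_d0(length: int) -> float:
    """Nucleic-acid TM-score length normalization, floored at 0.5 A."""
    if length <= 0:
        raise ValueError("length must be positive")
    return max(0.5, 0.6 * np.sqrt(length - 0.5) - 2.5)


def tm_score(pred, ref) -> float:
    """TM-score between two CG RNA structures on their C4' beads.

    Inputs are :class:`~rnacodesign.cg_io.CGRNAStructure` or raw ``(L, 3, 3)``
    arrays.  Residue correspondence is the identity mapping (designs are
    co-indexed with their targets); structures of unequal length are
    truncated to the common length with a warning.  The pair is Kabsch
    superposed on the C4' beads first, then
    ``TM = (1/L_ref) * sum_i 1 / (1 + (d_i/d0)^2)`` with the nucleic-acid
    d0(L).
    """
    import logging

    pc = np.asarray(getattr(pred, "coords", pred), dtype=float)
    rc = np.asarray(getattr(ref, "coords", ref), dtype=float)
    if pc.ndim != 3 or rc.ndim != 3:
        raise ValueError("tm_score expects (L, 3, 3) bead arrays")
    l_ref = rc.shape[0]
    if pc.shape[0] != l_ref:
        logging.getLogger(__name__).warning(
            "tm_score: length mismatch %d vs %d, truncating", pc.shape[0], l_ref)
    l_common = min(pc.shape[0], l_ref)
    if l_common < 3:
        raise ValueError("tm_score needs at least 3 residues")
    c4_pred = pc[:l_common, 1]
    c4_ref = rc[:l_common, 1]
    _, aligned = kabsch_align(c4_pred, c4_ref)
    d = np.linalg.norm(aligned - c4_ref, axis=1)
    d0 = tm_d0(l_ref)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)
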