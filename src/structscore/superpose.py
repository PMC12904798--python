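"""Rigid-body superposition (Kabsch) and RMSD helpers."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping ``mobile`` onto ``target``.

    Both arrays are (n, 3) with n >= 1; the returned transform minimizes
    ``||(mobile @ R.T + t) - target||``.  Proper rotation is enforced
    (no reflections).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch requires matching (n, 3) coordinate arrays")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Minimal RMSD after optimal rigid superposition."""
    if len(mobile) < 3:
        raise ValueError("superposition requires at least 3 positions")
    rot, trans = kabsch(mobile, target)
    return rmsd(apply_transform(mobile, rot, trans), target)
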