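"""Low-level geometry helpers: Kabsch superposition and sphere point sets."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to ``reference``.
    Proper rotations only (reflections are corrected by flipping the sign of
    the smallest singular vector).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    h = (mobile - mu_m).T @ (reference - mu_r)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = mu_r - rot @ mu_m
    return rot, trans


def superpose(mobile: np.ndarray, reference: np.ndarray,
              apply_to: np.ndarray | None = None) -> np.ndarray:
    """Superpose ``mobile`` onto ``reference`` and return the transformed
    coordinates of ``apply_to`` (defaults to ``mobile`` itself)."""
    rot, trans = kabsch(mobile, reference)
    target = mobile if apply_to is None else np.asarray(apply_to, dtype=float)
    return target @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equally shaped (n, 3) arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def fitted_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal (Kabsch) superposition."""
    return rmsd(superpose(mobile, reference), reference)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden spiral).

    Used as the quadrature grid of the Shrake-Rupley surface-area
    calculation; the set is fixed for a given ``n`` so repeated runs are
    bit-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + 5.0 ** 0.5)
    theta = golden * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )
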