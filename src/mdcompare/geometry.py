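"""Rigid-body superposition (Kabsch) and RMSD primitives."""
from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "kabsch_batch", "apply_fit", "rmsd", "fit_rmsd"]


def kabsch(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation/translation of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``reference`` in the least-squares sense.  The rotation is always a
    proper rotation (``det R = +1``); reflections are never used.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must share shape (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    P = mobile - mu_m
    Q = reference - mu_r
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - mu_m @ R.T
    fitted = mobile @ R.T + t
    value = rmsd(fitted, reference)
    return R, t, value


def kabsch_batch(
    frames: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Kabsch of many frames against one reference.

    ``frames`` has shape (n, m, 3); returns stacked rotations (n, 3, 3),
    translations (n, 3) and RMSD values (n,).  Equivalent to calling
    :func:`kabsch` per frame but uses one stacked SVD.
    """
    frames = np.asarray(frames, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[1:] != reference.shape:
        raise ValueError("frames must have shape (n, m, 3) matching reference")
    if reference.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    mu_f = frames.mean(axis=1, keepdims=True)
    mu_r = reference.mean(axis=0)
    P = frames - mu_f
    Q = reference - mu_r
    H = np.einsum("nmi,mj->nij", P, Q)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("nij,nkj->nik", Vt, U)))
    D = np.zeros((len(frames), 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("nji,njk,nlk->nil", Vt, D, U)
    t = mu_r - np.einsum("nij,nj->ni", R, mu_f[:, 0, :])
    m = reference.shape[0]
    msd = (
        np.sum(P ** 2, axis=(1, 2))
        + np.sum(Q ** 2)
        - 2 * (S[:, 0] + S[:, 1] + d * S[:, 2])
    ) / m
    return R, t, np.sqrt(np.clip(msd, 0.0, None))


def apply_fit(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply a rotation/translation to an (n, 3) coordinate array."""
    return np.asarray(coords) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def fit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rigid motions (superposed RMSD)."""
    return kabsch(mobile, reference)[2]
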