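"""Small geometry kernel shared across modules.

Rigid-body superposition (Kabsch), quaternion helpers, internal-coordinate
atom placement (NeRF) and deterministic point sets on S2 / SO(3).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "kabsch",
    "kabsch_rmsd",
    "apply_rigid",
    "quat_to_matrix",
    "matrix_to_quat",
    "place_atom",
    "dihedral",
    "angle",
    "fibonacci_sphere",
    "super_fibonacci_rotations",
]


def kabsch(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal rigid transform (R, t) minimising weighted RMSD.

    Returns (R, t, rmsd) such that ``mobile @ R.T + t`` best fits
    ``reference``. Proper rotation only (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms for superposition")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(0) / wsum
    cr = (w[:, None] * reference).sum(0) / wsum
    x = mobile - cm
    y = reference - cr
    h = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # rank-deficient (collinear) point sets leave the rotation underdetermined
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("paired atoms are collinear; superposition is degenerate")
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = cr - rot @ cm
    fitted = x @ rot.T + cr
    rmsd = float(np.sqrt((w[:, None] * (fitted - reference) ** 2).sum() / wsum))
    return rot, t, rmsd


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations of the same atoms."""
    return kabsch(a, b)[2]


def apply_rigid(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(rot).T + np.asarray(trans)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) -> 3x3 rotation matrix."""
    w, x, y, z = np.asarray(q, dtype=float) / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix -> unit quaternion (w, x, y, z), w >= 0."""
    m = np.asarray(m, dtype=float)
    tr = np.trace(m)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(m)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(1.0 + m[i, i] - m[j, j] - m[k, k], 0.0)) * 2
        q = np.empty(4)
        q[0] = (m[k, j] - m[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (m[j, i] + m[i, j]) / s
        q[1 + k] = (m[k, i] + m[i, k]) / s
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def dihedral(a, b, c, d) -> float:
    """Signed torsion a-b-c-d in degrees, IUPAC convention."""
    b0 = np.asarray(a, float) - np.asarray(b, float)
    b1 = np.asarray(c, float) - np.asarray(b, float)
    b2 = np.asarray(d, float) - np.asarray(c, float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, length: float, ang: float, tors: float) -> np.ndarray:
    """NeRF placement: position D given A-B-C with |C-D|=length,
    angle(B,C,D)=ang and torsion(A,B,C,D)=tors (degrees)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang_r = np.radians(ang)
    tor_r = np.radians(tors)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(ang_r),
            length * np.sin(ang_r) * np.cos(tor_r),
            length * np.sin(ang_r) * np.sin(tor_r),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-angle spiral)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def super_fibonacci_rotations(n: int) -> np.ndarray:
    """Deterministic quasi-uniform covering of SO(3) as quaternions (n, 4).

    Super-Fibonacci spiral construction (Alexa 2022). The identity rotation
    is prepended so a 'no rotation' hypothesis is always explored.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([[1.0, 0.0, 0.0, 0.0]])
    m = n - 1
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041  # positive root of x^4 = x + 4
    i = np.arange(m, dtype=float)
    s = i + 0.5
    r = np.sqrt(s / m)
    rr = np.sqrt(1.0 - s / m)
    alpha = 2.0 * np.pi * s / phi
    beta = 2.0 * np.pi * s / psi
    q = np.column_stack(
        [r * np.sin(alpha), r * np.cos(alpha), rr * np.sin(beta), rr * np.cos(beta)]
    )
    return np.vstack([[1.0, 0.0, 0.0, 0.0], q])
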