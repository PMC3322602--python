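"""Small geometric measures shared by completion and the idealizer."""

from __future__ import annotations

import numpy as np


def distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle_deg(a, b, c) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_deg(a, b, c, d) -> float:
    """Torsion angle a-b-c-d in degrees, in (-180, 180]."""
    p = [np.asarray(x, float) for x in (a, b, c, d)]
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0:
        return 0.0
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / nb2)
    return float(np.degrees(np.arctan2(y, x)))


def wrap_periodic_dev(theta: float, target: float, period: int) -> float:
    """Deviation (degrees) from the nearest minimum of a periodic torsion
    restraint whose minima sit at target + k*360/period."""
    m = 360.0 / max(int(period), 1)
    return (theta - target + m / 2.0) % m - m / 2.0


def best_fit_plane(points: np.ndarray, weights=None):
    """Weighted least-squares plane through ``points`` (n x 3).

    Returns (unit normal, centroid).  The normal is the eigenvector of the
    weighted covariance with the smallest eigenvalue.
    """
    pts = np.asarray(points, float)
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    centroid = (pts * w[:, None]).sum(axis=0)
    d = pts - centroid
    cov = (d * w[:, None]).T @ d
    vals, vecs = np.linalg.eigh(cov)
    normal = vecs[:, 0]
    return normal, centroid
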