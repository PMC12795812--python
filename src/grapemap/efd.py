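"""Elliptical Fourier descriptors (EFD) for closed contours.

Classical chain-free EFD of a closed polygonal contour: the boundary is
treated as a piecewise-linear closed curve traversed at constant speed and
each coordinate is expanded in a truncated Fourier series.  Harmonic ``n``
contributes four coefficients ``(a_n, b_n, c_n, d_n)``.

Normalization follows the usual first-harmonic procedure: the starting
point is rotated so the first-harmonic phase is zero, the shape is rotated
so the first-harmonic semi-major axis lies on the +x axis, and all
coefficients are divided by that semi-major axis length.  The normalized
descriptor is invariant to rotation, scale and starting point; after
normalization ``a_1 == 1`` and ``b_1 == 0`` up to floating-point tolerance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "elliptic_fourier_coefficients",
    "normalize_coefficients",
    "efd_locus",
    "efd_reconstruct",
    "efd_descriptor",
]


def _closed(contour: np.ndarray) -> np.ndarray:
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be (n, 2)")
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    return pts


def elliptic_fourier_coefficients(contour: np.ndarray, harmonics: int = 10) -> np.ndarray:
    """Raw EFD coefficients of a closed contour.

    Parameters
    ----------
    contour : (n, 2) array of boundary points (closed or open ring).
    harmonics : number of harmonics H.

    Returns
    -------
    (H, 4) array of rows (a_n, b_n, c_n, d_n): a/b multiply cos/sin for x,
    c/d for y.
    """
    pts = _closed(contour)
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    if len(dt) < 3:
        raise ValueError("degenerate contour: fewer than 3 distinct points")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValueError("degenerate contour: zero perimeter")
    n = np.arange(1, harmonics + 1)[:, None]  # (H, 1)
    phi = 2.0 * np.pi * t / T
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (H, m)
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * np.pi**2 * n**2)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = (const * (dxdt * dcos)).sum(axis=1)
    b = (const * (dxdt * dsin)).sum(axis=1)
    c = (const * (dydt * dcos)).sum(axis=1)
    dd = (const * (dydt * dsin)).sum(axis=1)
    return np.column_stack([a, b, c, dd])


def elliptic_fourier_coefficients_batch(contours: np.ndarray, harmonics: int = 10) -> np.ndarray:
    """EFD coefficients for a batch of equal-length closed contours.

    ``contours`` is (m, n, 2) with no repeated closing point; returns
    (m, H, 4).  Identical to looping :func:`elliptic_fourier_coefficients`
    but one set of matrix products for the whole batch.
    """
    pts = np.asarray(contours, dtype=float)
    closed = np.concatenate([pts, pts[:, :1]], axis=1)  # (m, n+1, 2)
    d = np.diff(closed, axis=1)  # (m, n, 2)
    dt = np.hypot(d[..., 0], d[..., 1])  # (m, n)
    if (dt <= 0).any():
        # fall back to the per-contour path, which drops zero-length segments
        return np.stack([elliptic_fourier_coefficients(c, harmonics) for c in pts])
    t = np.concatenate([np.zeros((len(pts), 1)), np.cumsum(dt, axis=1)], axis=1)
    T = t[:, -1:]
    nvec = np.arange(1, harmonics + 1)[None, :, None]  # (1, H, 1)
    phi = (2.0 * np.pi * t / T)[:, None, :]  # (m, 1, n+1)
    dcos = np.cos(nvec * phi[..., 1:]) - np.cos(nvec * phi[..., :-1])  # (m, H, n)
    dsin = np.sin(nvec * phi[..., 1:]) - np.sin(nvec * phi[..., :-1])
    const = T[:, :, None] / (2.0 * np.pi**2 * nvec**2)  # (m, H, 1)
    dxdt = (d[..., 0] / dt)[:, None, :]
    dydt = (d[..., 1] / dt)[:, None, :]
    a = (const * dxdt * dcos).sum(axis=2)
    b = (const * dxdt * dsin).sum(axis=2)
    c = (const * dydt * dcos).sum(axis=2)
    dd = (const * dydt * dsin).sum(axis=2)
    return np.stack([a, b, c, dd], axis=2)


def normalize_coefficients(coeffs: np.ndarray) -> np.ndarray:
    """Rotation-, scale- and start-point-invariant normalization.

    Operates on the output of :func:`elliptic_fourier_coefficients`.
    """
    co = np.array(coeffs, dtype=float)
    a1, b1, c1, d1 = co[0]
    # start-point phase from the first harmonic
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 - b1**2 + c1**2 - d1**2)
    n = np.arange(1, len(co) + 1)
    cn, sn = np.cos(n * theta), np.sin(n * theta)
    rotated = np.empty_like(co)
    rotated[:, 0] = co[:, 0] * cn + co[:, 1] * sn
    rotated[:, 1] = -co[:, 0] * sn + co[:, 1] * cn
    rotated[:, 2] = co[:, 2] * cn + co[:, 3] * sn
    rotated[:, 3] = -co[:, 2] * sn + co[:, 3] * cn
    # orientation of the first-harmonic semi-major axis
    psi = np.arctan2(rotated[0, 2], rotated[0, 0])
    cp, sp = np.cos(psi), np.sin(psi)
    rot = np.array([[cp, sp], [-sp, cp]])
    out = np.empty_like(rotated)
    for i in range(len(co)):
        m = rot @ np.array([[rotated[i, 0], rotated[i, 1]], [rotated[i, 2], rotated[i, 3]]])
        out[i] = m.ravel()
    scale = out[0, 0]
    if scale == 0:
        raise ValueError("degenerate first harmonic")
    out /= abs(scale)
    if out[0, 0] < 0:
        # half-turn ambiguity of the major axis: fold onto a_1 > 0
        sign = np.where(np.arange(1, len(co) + 1) % 2 == 1, -1.0, 1.0)
        out *= sign[:, None]
    # the joint half-turn of start point and orientation leaves the first
    # harmonic fixed but flips the sign of every even harmonic; canonicalize
    # by making the dominant even-harmonic coefficient positive
    if len(out) > 1:
        evens = out[1::2]
        if evens.size:
            flat = evens.ravel()
            j = int(np.argmax(np.abs(flat)))
            if abs(flat[j]) > 1e-12 and flat[j] < 0:
                out[1::2] *= -1.0
    return out


def efd_locus(contour: np.ndarray) -> tuple[float, float]:
    """DC terms (A0, C0) of the expansion — the curve's parametric centre."""
    pts = _closed(contour)
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    mid = (pts[:-1][keep] + pts[1:][keep]) / 2.0
    T = dt.sum()
    return float((mid[:, 0] * dt).sum() / T), float((mid[:, 1] * dt).sum() / T)


def efd_reconstruct(coeffs: np.ndarray, n_points: int = 256, locus: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Reconstruct contour points from EFD coefficients."""
    co = np.asarray(coeffs, dtype=float)
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, len(co) + 1)[:, None]
    arg = 2.0 * np.pi * n * t
    cosv, sinv = np.cos(arg), np.sin(arg)
    x = locus[0] + co[:, 0] @ cosv + co[:, 1] @ sinv
    y = locus[1] + co[:, 2] @ cosv + co[:, 3] @ sinv
    return np.column_stack([x, y])


def efd_descriptor(contour: np.ndarray, harmonics: int = 10) -> np.ndarray:
    """Flat normalized descriptor vector of length 4*H for a closed contour."""
    if len(np.asarray(contour)) < 3 * harmonics:
        raise ValueError(f"need >= {3 * harmonics} boundary points for {harmonics} harmonics; resample the contour")
    return normalize_coefficients(elliptic_fourier_coefficients(contour, harmonics)).ravel()
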