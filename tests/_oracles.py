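"""Independent oracles used by the test suite.

Everything here is deliberately coded from first principles, without reusing
the package's implementation paths:

* ``geselowitz_field``: numerical evaluation of the conducting-sphere dipole
  field by integrating the secondary (volume-current) contribution as a
  surface integral of the boundary potential, with the potential built from
  a spherical-harmonic Neumann-series solution.
* ``brute_force_scan``: exhaustive beamformer power scan over grid points
  and a dense orientation fan.
* ``enumerate_lattice``: triple-loop enumeration of the clipped source grid.
* ``sphere_center_grid_search``: coarse grid search for the least-squares
  sphere fit objective.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import sph_harm_y

MU0_OVER_4PI = 1e-7


def _rot_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector v onto +z (Rodrigues)."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(v @ z)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    ax = axis / s
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + s * K + (1 - c) * K @ K


def _solid_harm(l: int, m: int, pts: np.ndarray) -> np.ndarray:
    """Solid harmonic r^l * conj(Y_lm) at cartesian points (n, 3)."""
    r = np.linalg.norm(pts, axis=1)
    theta = np.arccos(np.clip(pts[:, 2] / np.maximum(r, 1e-300), -1, 1))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    return r**l * np.conj(sph_harm_y(l, m, theta, phi))


def geselowitz_field(
    center_m: np.ndarray,
    radius_m: float,
    source_m: np.ndarray,
    moment_am: np.ndarray,
    sensor_m: np.ndarray,
    lmax: int | None = None,
    ntheta: int = 160,
    nphi: int = 320,
) -> np.ndarray:
    """Field vector (tesla) at one sensor, all inputs in SI metres / A·m.

    B = B_primary - (mu0/4pi) * surface integral of V n x (r - r') / |r - r'|^3,
    where V on the boundary solves the interior Neumann problem.  The dipole
    is rotated onto the +z axis so only |m| <= 1 harmonics contribute; the
    series coefficients come from numerical gradients of solid harmonics.
    """
    r0 = np.asarray(source_m, float) - center_m
    rs = np.asarray(sensor_m, float) - center_m
    R = _rot_to_z(r0)
    r0r, rsr, qr = R @ r0, R @ rs, R @ np.asarray(moment_am, float)

    d = rsr - r0r
    b_primary = MU0_OVER_4PI * np.cross(qr, d) / np.linalg.norm(d) ** 3

    if lmax is None:
        # series terms decay like (|r0|/R)^l; truncate at 1e-8 relative
        ratio = max(np.linalg.norm(r0) / radius_m, 0.3)
        lmax = min(90, int(np.ceil(np.log(1e-8) / np.log(ratio))) + 5)

    h = 1e-6 * radius_m
    ls = np.arange(1, lmax + 1)
    clm = np.zeros((lmax, 3), complex)  # columns: m = -1, 0, 1
    for mi, m in enumerate((-1, 0, 1)):
        grad = np.zeros((lmax, 3), complex)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            for li, l in enumerate(ls):
                grad[li, ax] = (
                    _solid_harm(l, m, (r0r + e)[None])[0]
                    - _solid_harm(l, m, (r0r - e)[None])[0]
                ) / (2 * h)
        clm[:, mi] = (grad @ qr) / (2 * ls + 1)

    x, wx = leggauss(ntheta)  # nodes in cos(theta)
    phi = (np.arange(nphi) + 0.5) * 2 * np.pi / nphi
    wphi = 2 * np.pi / nphi
    ct = x
    st = np.sqrt(1 - ct**2)
    theta = np.arccos(ct)

    V = np.zeros((ntheta, nphi))
    fac = (2 * ls + 1) / (ls * radius_m ** (ls + 1.0))
    for mi, m in enumerate((-1, 0, 1)):
        # separable in theta/phi: Y_lm(theta, phi) = Y_lm(theta, 0) e^{i m phi}
        y_theta = sph_harm_y(ls[:, None], m, theta[None, :], 0.0)  # (lmax, ntheta)
        prof = (clm[:, mi] * fac) @ y_theta                         # (ntheta,)
        V += np.real(prof[:, None] * np.exp(1j * m * phi)[None, :])

    n_hat = np.stack(
        [
            st[:, None] * np.cos(phi)[None, :],
            st[:, None] * np.sin(phi)[None, :],
            np.broadcast_to(ct[:, None], (ntheta, nphi)),
        ],
        axis=-1,
    )
    pts = radius_m * n_hat
    diff = rsr[None, None, :] - pts
    dist3 = np.linalg.norm(diff, axis=-1) ** 3
    integrand = np.cross(n_hat, diff) / dist3[..., None] * V[..., None]
    dS = radius_m**2 * wx[:, None] * wphi
    b_secondary = -MU0_OVER_4PI * np.sum(integrand * dS[..., None], axis=(0, 1))
    return R.T @ (b_primary + b_secondary)


def geselowitz_projection(sphere, source_mm, moment_am, sensor_mm, sensor_ori, **kw) -> float:
    """Oracle counterpart of dipole_field (mm inputs, projection on sensor axis)."""
    b = geselowitz_field(
        sphere.center * 1e-3,
        sphere.radius * 1e-3,
        np.asarray(source_mm, float) * 1e-3,
        np.asarray(moment_am, float),
        np.asarray(sensor_mm, float) * 1e-3,
        **kw,
    )
    return float(b @ np.asarray(sensor_ori, float))


def brute_force_scan(cov: np.ndarray, leadfields: np.ndarray, regularization: float,
                     n_orientations: int = 3600) -> tuple[int, np.ndarray]:
    """Exhaustive beamformer power scan.

    ``leadfields``: (n_ch, n_points, 3).  For each point the radial direction
    of a spherical conductor is magnetically silent, so any scalar beamformer
    must search the sensed (non-silent) subspace; here that subspace comes
    from an SVD of L (right singular vectors with non-negligible singular
    values) and is scanned with a dense angular fan.  Power along unit theta
    is 1 / (theta^T L^T Creg^-1 L theta).  Returns (argmax point index,
    per-point max power).
    """
    creg = cov + regularization * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
    cinv = np.linalg.inv(creg)
    angles = np.linspace(0.0, np.pi, n_orientations, endpoint=False)
    n_points = leadfields.shape[1]
    power = np.zeros(n_points)
    for p in range(n_points):
        L = leadfields[:, p, :]
        _, sv, vt = np.linalg.svd(L, full_matrices=False)
        sensed = vt[sv > np.sqrt(1e-7) * sv[0]]  # matches the silent-eig cut on M
        if len(sensed) == 2:
            fan = (np.cos(angles)[:, None] * sensed[0]
                   + np.sin(angles)[:, None] * sensed[1])
        elif len(sensed) == 3:  # no silent direction: dense fan on the sphere
            i = np.arange(n_orientations)
            z = 1 - 2 * (i + 0.5) / n_orientations
            r = np.sqrt(1 - z**2)
            golden = np.pi * (3 - np.sqrt(5))
            fan = np.column_stack([r * np.cos(golden * i), r * np.sin(golden * i), z])
        else:
            fan = sensed
        proj = L @ fan.T                      # (n_ch, n_orientations)
        denom = np.einsum("co,cd,do->o", proj, cinv, proj)
        power[p] = (1.0 / denom).max()
    return int(np.argmax(power)), power


def enumerate_lattice(center: np.ndarray, radius: float, spacing: float,
                      margin: float) -> int:
    """Triple-loop count of half-offset lattice points within radius - margin."""
    rmax = radius - margin
    count = 0
    n = int(np.floor(rmax / spacing + 0.5))
    for i in range(-n, n):
        for j in range(-n, n):
            for k in range(-n, n):
                p = (np.array([i + 0.5, j + 0.5, k + 0.5])) * spacing
                if np.sqrt(np.sum(p**2)) <= rmax + 1e-9:
                    count += 1
    return count


def sphere_center_grid_search(points: np.ndarray, center0: np.ndarray,
                              half_width: float = 5.0, step: float = 1.0):
    """Best (center, radius) over a coarse center lattice, radius = mean distance."""
    best = (None, None, np.inf)
    offsets = np.arange(-half_width, half_width + step / 2, step)
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                c = center0 + np.array([dx, dy, dz])
                d = np.linalg.norm(points - c, axis=1)
                r = d.mean()
                sse = np.sum((d - r) ** 2)
                if sse < best[2]:
                    best = (c, r, sse)
    return best
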