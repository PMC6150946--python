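"""Magnetic forward model: current dipole inside a homogeneous conducting sphere.

The analytic spherical-conductor solution is used in place of a
subject-specific single-shell model (for a spherical boundary the two
coincide).  Only the projection of the field onto each sensor's axis is
returned, matching radial-axis magnetometers.

Units: positions in millimetres, dipole moments in ampere-metre, fields in
tesla.  Internally everything is converted to SI metres.

Notable properties of the spherical solution, relied on by tests:

* purely radial dipoles are magnetically silent outside the conductor;
* the external field depends on the sphere *center* only, not its radius;
* the field is linear in the dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import DomainError
from .geometry import ConductorSphere, SensorArray, SourceGrid

MU0_OVER_4PI = 1e-7  # T·m/A
_MM = 1e-3


@dataclass
class LeadFieldSet:
    """Channel-space lead fields for unit Cartesian dipole moments at grid points.

    ``fields[c, p, a]`` is the field (tesla) at scalp channel ``c`` from a
    1 A·m dipole along Cartesian axis ``a`` at grid point ``p``.  Reference
    channels are excluded: at ~30 cm their brain lead field is orders of
    magnitude below sensor noise and is treated as exactly zero.
    """

    fields: np.ndarray  # (n_scalp, n_points, 3)
    array: SensorArray
    grid: SourceGrid
    sphere: ConductorSphere

    @property
    def matrix(self) -> np.ndarray:
        """(n_scalp, 3 * n_points) view, point-major column blocks."""
        n_scalp, n_points, _ = self.fields.shape
        return self.fields.reshape(n_scalp, n_points * 3)

    def point_leadfield(self, index: int) -> np.ndarray:
        """(n_scalp, 3) lead field of one grid point."""
        return self.fields[:, index, :]


def _sarvas_field(
    center_m: np.ndarray,
    source_m: np.ndarray,
    moment_am: np.ndarray,
    sensor_m: np.ndarray,
) -> np.ndarray:
    """Vector field (tesla) of a current dipole in a homogeneous sphere.

    All inputs in SI metres / ampere-metres; ``sensor_m`` may be (n, 3).
    """
    r = np.atleast_2d(sensor_m) - center_m          # (n, 3)
    r0 = source_m - center_m                        # (3,)
    a_vec = r - r0                                  # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise DomainError("sensor collocated with source")
    ar = np.einsum("ij,ij->i", a_vec, r)            # a·r
    r0r = r @ r0                                    # r0·r
    F = a * (rn * a + rn**2 - r0r)
    gradF = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + ar / a)[:, None] * r0
    )
    qxr0 = np.cross(moment_am, r0)                  # (3,)
    qxr0_dot_r = r @ qxr0
    B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0 - qxr0_dot_r[:, None] * gradF)
    return B


def dipole_field(
    sphere: ConductorSphere,
    source_pos: np.ndarray,
    moment: np.ndarray,
    sensor_pos: np.ndarray,
    sensor_ori: np.ndarray,
) -> float:
    """Field (tesla) along ``sensor_ori`` from a dipole ``moment`` (A·m) at ``source_pos`` (mm).

    The source must lie strictly inside the conductor sphere and the sensor
    strictly outside.
    """
    source_pos = np.asarray(source_pos, float)
    sensor_pos = np.asarray(sensor_pos, float)
    d_src = np.linalg.norm(source_pos - sphere.center)
    if d_src >= sphere.radius:
        raise DomainError(
            f"source at distance {d_src:.2f} mm is not strictly inside the sphere "
            f"(radius {sphere.radius:.2f} mm)"
        )
    d_sens = np.linalg.norm(sensor_pos - sphere.center)
    if d_sens <= sphere.radius:
        raise DomainError(
            f"sensor at distance {d_sens:.2f} mm is not strictly outside the sphere "
            f"(radius {sphere.radius:.2f} mm)"
        )
    B = _sarvas_field(
        sphere.center * _MM, source_pos * _MM, np.asarray(moment, float), sensor_pos[None, :] * _MM
    )
    return float(B[0] @ np.asarray(sensor_ori, float))


def compute_leadfields(
    array: SensorArray, grid: SourceGrid, sphere: ConductorSphere
) -> LeadFieldSet:
    """Lead fields for unit dipoles along x, y, z at every grid point.

    Raises :class:`DomainError` naming the offending grid point if any point
    lies outside the sphere (scalp sensors are checked up front).
    """
    scalp = array.scalp_indices
    sens_pos = array.positions[scalp] * _MM
    sens_ori = array.orientations[scalp]
    d_sens = np.linalg.norm(array.positions[scalp] - sphere.center, axis=1)
    if np.any(d_sens <= sphere.radius):
        bad = int(np.argmin(d_sens))
        raise DomainError(
            f"scalp sensor {array.labels[scalp[bad]]!r} lies inside the conductor sphere"
        )
    d_src = np.linalg.norm(grid.points - sphere.center, axis=1)
    if np.any(d_src >= sphere.radius):
        bad = int(np.argmax(d_src))
        raise DomainError(f"grid point {bad} lies outside the conductor sphere")

    n_points = grid.n_points
    fields = np.empty((len(scalp), n_points, 3))
    eye = np.eye(3)
    for p in range(n_points):
        for axis in range(3):
            B = _sarvas_field(sphere.center * _MM, grid.points[p] * _MM, eye[axis], sens_pos)
            fields[:, p, axis] = np.einsum("ij,ij->i", B, sens_ori)
    return LeadFieldSet(fields=fields, array=array, grid=grid, sphere=sphere)


def save_leadfields(lf: LeadFieldSet, path) -> None:
    """Store under /leadfields with shape/unit/provenance attributes."""
    import h5py

    with h5py.File(path, "a") as f:
        if "leadfields" in f:
            del f["leadfields"]
        g = f.create_group("leadfields")
        d = g.create_dataset("fields", data=lf.fields)
        d.attrs["units"] = "tesla per ampere-metre"
        d.attrs["axes"] = "scalp_channel, grid_point, cartesian_moment_axis"
        g.create_dataset("grid_points_mm", data=lf.grid.points)
        g.attrs["grid_spacing_mm"] = lf.grid.spacing
        g.attrs["sphere_center_mm"] = lf.sphere.center
        g.attrs["sphere_radius_mm"] = lf.sphere.radius
        g.create_dataset(
            "scalp_labels",
            data=np.array([lf.array.labels[i] for i in lf.array.scalp_indices], dtype="S"),
        )


def point_leadfield(
    array: SensorArray, sphere: ConductorSphere, source_pos: np.ndarray
) -> np.ndarray:
    """(n_scalp, 3) lead field at an arbitrary (off-grid) source position."""
    scalp = array.scalp_indices
    sens_pos = array.positions[scalp] * _MM
    sens_ori = array.orientations[scalp]
    out = np.empty((len(scalp), 3))
    for axis in range(3):
        B = _sarvas_field(
            sphere.center * _MM, np.asarray(source_pos, float) * _MM, np.eye(3)[axis], sens_pos
        )
        out[:, axis] = np.einsum("ij,ij->i", B, sens_ori)
    return out
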