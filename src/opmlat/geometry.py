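"""Sensor-array and source-grid geometry.

Everything lives in a single MNI-aligned head frame, in millimetres.  Scalp
sensors sense the radial field component only; their ``orientation`` is the
unit sensing axis.  Reference sensors sit far from the head and see only
environmental interference.

The default helmet produced by :func:`default_sensor_array` is a stand-in
layout (quasi-uniform frontotemporal coverage of both hemispheres); no real
sensor coordinates ship with this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._exceptions import ConfigurationError, FormatError, GeometryError, ValidationError

SCALP = "scalp"
REFERENCE = "reference"

#: channels with |x| below this are "midline" and excluded from hemisphere counts
HEMISPHERE_EPS_MM = 0.5

_SENSOR_COLUMNS = ["label", "x_mm", "y_mm", "z_mm", "ox", "oy", "oz", "role"]


@dataclass
class SensorArray:
    """Positions and sensing axes of scalp + reference magnetometers."""

    labels: list[str]
    positions: np.ndarray          # (n, 3) mm
    orientations: np.ndarray       # (n, 3) unit vectors
    roles: list[str]               # "scalp" | "reference" per channel
    sampling_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = len(self.labels)
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ValidationError("positions/orientations must have shape (n_channels, 3)")
        if len(self.roles) != n:
            raise ValidationError("one role per channel required")
        bad = set(self.roles) - {SCALP, REFERENCE}
        if bad:
            raise FormatError(f"unknown channel roles: {sorted(bad)}")
        norms = np.linalg.norm(self.orientations, axis=1)
        off = np.abs(norms - 1.0)
        if np.any(off > 1e-6):
            idx = int(np.argmax(off))
            raise ValidationError(
                f"orientation of channel {self.labels[idx]!r} has norm {norms[idx]:.6g}, not unit"
            )
        # renormalize small drift so downstream code can rely on 1e-9 unit norms
        self.orientations = self.orientations / norms[:, None]

    # -- channel bookkeeping -------------------------------------------------

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == SCALP], dtype=int)

    @property
    def reference_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == REFERENCE], dtype=int)

    @property
    def n_scalp(self) -> int:
        return len(self.scalp_indices)

    @property
    def n_reference(self) -> int:
        return len(self.reference_indices)

    def mirror_x(self) -> "SensorArray":
        """Return the array reflected through the x = 0 plane (orientation x flipped too)."""
        flip = np.array([-1.0, 1.0, 1.0])
        return SensorArray(
            labels=list(self.labels),
            positions=self.positions * flip,
            orientations=self.orientations * flip,
            roles=list(self.roles),
            sampling_rate=self.sampling_rate,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
                "ox": self.orientations[:, 0],
                "oy": self.orientations[:, 1],
                "oz": self.orientations[:, 2],
                "role": self.roles,
            }
        )


def save_sensor_array(array: SensorArray, path: str | Path, format: str | None = None) -> None:
    """Write a sensor table as TSV or JSON (schema: label,x_mm,y_mm,z_mm,ox,oy,oz,role)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "tsv")
    df = array.to_frame()
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "json":
        payload = {
            "sampling_rate": array.sampling_rate,
            "channels": df.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise FormatError(f"unknown sensor-array format {fmt!r}")


def load_sensor_array(
    path: str | Path, format: str | None = None, sampling_rate: float = 1000.0
) -> SensorArray:
    """Load and validate a sensor array from TSV or JSON.

    Orientations whose norm deviates from 1 by less than 1e-6 are silently
    renormalized; larger deviations raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif fmt == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["channels"])
        sampling_rate = float(payload.get("sampling_rate", sampling_rate))
    else:
        raise FormatError(f"unknown sensor-array format {fmt!r}")
    missing = [c for c in _SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sensor table {path} is missing columns: {missing}")
    return SensorArray(
        labels=[str(x) for x in df["label"]],
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        orientations=df[["ox", "oy", "oz"]].to_numpy(float),
        roles=[str(r) for r in df["role"]],
        sampling_rate=sampling_rate,
    )


@dataclass
class ConductorSphere:
    """Homogeneous conducting sphere standing in for the inner-skull boundary."""

    center: np.ndarray  # (3,) mm
    radius: float       # mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not self.radius > 0:
            raise GeometryError(f"sphere radius must be > 0, got {self.radius}")

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        d = np.linalg.norm(np.atleast_2d(points) - self.center, axis=1)
        return d < self.radius - margin


def fit_conductor_sphere(
    scalp_positions: np.ndarray, margin: float = 15.0
) -> ConductorSphere:
    """Least-squares sphere through scalp sensor positions, shrunk by ``margin`` mm.

    The fit minimizes squared radial residuals (geometric fit, Gauss-Newton from
    an algebraic initial estimate).  The shrink models the scalp-to-inner-skull
    distance since no anatomical surface is available.
    """
    pts = np.asarray(scalp_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise GeometryError("need at least 4 scalp positions (n, 3)")
    # algebraic (Coope) initialization: ||p||^2 = 2 c.p + (r^2 - c.c)
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts**2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise GeometryError("scalp positions are coplanar/degenerate; cannot fit a sphere")
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 0.0)))

    def radial_residuals(theta: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pts - theta[:3], axis=1) - theta[3]

    fit = least_squares(radial_residuals, np.append(c0, r0), method="lm")
    center, radius = fit.x[:3], float(fit.x[3])
    if radius - margin <= 0:
        raise GeometryError(
            f"fitted radius {radius:.1f} mm does not exceed the inner-skull margin {margin} mm"
        )
    return ConductorSphere(center=center, radius=radius - margin)


@dataclass
class ROISpec:
    """Ball-shaped region of interest (stand-in for an atlas label)."""

    name: str
    center: np.ndarray  # (3,) mm
    radius: float       # mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def mirrored(self, name: str) -> "ROISpec":
        return ROISpec(name=name, center=self.center * np.array([-1.0, 1.0, 1.0]), radius=self.radius)


@dataclass
class SourceGrid:
    """Regular volumetric lattice of candidate source locations inside the conductor."""

    points: np.ndarray              # (m, 3) mm
    spacing: float                  # mm
    hemispheres: np.ndarray         # (m,) "left" | "right" | "midline"
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (m,) bool
    sphere: ConductorSphere | None = None

    @property
    def n_points(self) -> int:
        return len(self.points)

    def mask_for(self, name: str) -> np.ndarray:
        try:
            return self.roi_masks[name]
        except KeyError:
            raise ConfigurationError(f"no ROI named {name!r}; have {sorted(self.roi_masks)}") from None

    def nearest_point(self, pos: np.ndarray) -> int:
        return int(np.argmin(np.linalg.norm(self.points - np.asarray(pos, float), axis=1)))


def _hemisphere_labels(points: np.ndarray, eps: float = HEMISPHERE_EPS_MM) -> np.ndarray:
    labels = np.where(points[:, 0] < -eps, "left", np.where(points[:, 0] > eps, "right", "midline"))
    return labels.astype(object)


def build_source_grid(
    sphere: ConductorSphere,
    spacing: float,
    roi_specs: list[ROISpec] | None = None,
    margin: float = 10.0,
) -> SourceGrid:
    """Cubic lattice clipped to radius - margin around the sphere center.

    The lattice is offset by half a spacing per axis, so no point coincides
    with the sphere center (where every dipole is magnetically silent) and
    none sits on the x = 0 midline; mirror symmetry in x is preserved.  All
    interior points are kept; ROI masks are balls around the given centers.
    """
    if not spacing > 0:
        raise ConfigurationError(f"grid spacing must be > 0, got {spacing}")
    rmax = sphere.radius - margin
    if rmax < 0:
        raise ConfigurationError(
            f"margin {margin} mm exceeds sphere radius {sphere.radius} mm"
        )
    nsteps = int(np.floor(rmax / spacing + 0.5))
    offsets = (np.arange(-nsteps, nsteps) + 0.5) * spacing
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + sphere.center
    keep = np.linalg.norm(lattice - sphere.center, axis=1) <= rmax + 1e-9
    points = lattice[keep]
    if len(points) == 0:
        raise ConfigurationError("source grid is empty; decrease spacing or margin")
    grid = SourceGrid(
        points=points,
        spacing=float(spacing),
        hemispheres=_hemisphere_labels(points),
        sphere=sphere,
    )
    for spec in roi_specs or []:
        if not sphere.contains(spec.center[None, :])[0]:
            raise ConfigurationError(f"ROI {spec.name!r} center lies outside the conductor sphere")
        grid.roi_masks[spec.name] = (
            np.linalg.norm(points - spec.center, axis=1) <= spec.radius + 1e-9
        )
    return grid


def save_source_grid(grid: SourceGrid, path: str | Path) -> None:
    payload = {
        "spacing": grid.spacing,
        "points": grid.points.tolist(),
        "hemispheres": list(grid.hemispheres),
        "roi_masks": {k: np.flatnonzero(v).tolist() for k, v in grid.roi_masks.items()},
        "sphere": None
        if grid.sphere is None
        else {"center": grid.sphere.center.tolist(), "radius": grid.sphere.radius},
    }
    Path(path).write_text(json.dumps(payload))


def load_source_grid(path: str | Path) -> SourceGrid:
    payload = json.loads(Path(path).read_text())
    points = np.asarray(payload["points"], dtype=float)
    masks = {}
    for name, idx in payload["roi_masks"].items():
        m = np.zeros(len(points), dtype=bool)
        m[np.asarray(idx, dtype=int)] = True
        masks[name] = m
    sphere = None
    if payload.get("sphere"):
        sphere = ConductorSphere(payload["sphere"]["center"], payload["sphere"]["radius"])
    return SourceGrid(
        points=points,
        spacing=float(payload["spacing"]),
        hemispheres=np.asarray(payload["hemispheres"], dtype=object),
        roi_masks=masks,
        sphere=sphere,
    )


# -- default stand-in helmet -------------------------------------------------

HEAD_CENTER_MM = np.array([0.0, -5.0, 20.0])
SCALP_RADIUS_MM = 92.0
SENSOR_OFFSET_MM = 6.5        # sensitive cell sits above the holder base
REFERENCE_DISTANCE_MM = 300.0  # reference array fixed well behind the head


def _cap_directions(n: int, axis: np.ndarray, half_angle_deg: float) -> np.ndarray:
    """Quasi-uniform unit vectors on a spherical cap via a Fibonacci spiral."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    cmin = np.cos(np.deg2rad(half_angle_deg))
    i = np.arange(n)
    cos_t = 1.0 - (1.0 - cmin) * (i + 0.5) / n
    sin_t = np.sqrt(1.0 - cos_t**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    # rotate local +z onto the cap axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s, c = np.linalg.norm(v), float(z @ axis)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return local @ R.T


def default_sensor_array(
    n_scalp: int = 26,
    n_reference: int = 4,
    sampling_rate: float = 1000.0,
    head_center: np.ndarray = HEAD_CENTER_MM,
    scalp_radius: float = SCALP_RADIUS_MM,
    offset: float = SENSOR_OFFSET_MM,
) -> SensorArray:
    """Stand-in helmet: frontotemporal patches over both hemispheres + posterior references.

    Scalp sensors sit ``offset`` mm radially above a sphere of ``scalp_radius``
    around ``head_center`` and sense the outward radial field.  The layout is
    exactly mirror-symmetric in x.
    """
    if n_scalp < 2 or n_scalp % 2:
        raise ConfigurationError("n_scalp must be an even count >= 2 (bilateral layout)")
    axis_left = np.array([-0.90, 0.30, 0.32])
    dirs_left = _cap_directions(n_scalp // 2, axis_left, half_angle_deg=52.0)
    dirs_right = dirs_left * np.array([-1.0, 1.0, 1.0])
    dirs = np.vstack([dirs_left, dirs_right])
    positions = head_center + (scalp_radius + offset) * dirs
    labels = [f"L{i+1:02d}" for i in range(n_scalp // 2)] + [
        f"R{i+1:02d}" for i in range(n_scalp // 2)
    ]
    roles = [SCALP] * n_scalp

    ref_local = np.array([[-40.0, 0.0, 0.0], [40.0, 0.0, 0.0], [-40.0, 0.0, 60.0], [40.0, 0.0, 60.0]])
    ref_ori = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
    if n_reference > 4:
        raise ConfigurationError("default layout supports at most 4 reference sensors")
    ref_pos = head_center + np.array([0.0, -REFERENCE_DISTANCE_MM, 0.0]) + ref_local[:n_reference]
    positions = np.vstack([positions, ref_pos])
    orientations = np.vstack([dirs, ref_ori[:n_reference]])
    labels += [f"REF{i+1}" for i in range(n_reference)]
    roles += [REFERENCE] * n_reference
    return SensorArray(
        labels=labels,
        positions=positions,
        orientations=orientations,
        roles=roles,
        sampling_rate=sampling_rate,
    )
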