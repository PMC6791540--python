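"""Virtual calliper and scanner measurements of voxel tumours.

The calliper emulation projects occupied voxels onto the base plane and
measures feret extents of the footprint: length is the maximal extent over
all horizontal directions (sampled at 1 degree), width is the extent
perpendicular to the length direction — mirroring how a second calliper jaw
is applied at right angles to the first.  Height is the full extent of the
tallest occupied voxel; footprint area is the projected voxel count.

Volume formulae:

* spheroid  V = (pi/6) * length * width^2        (calliper convention, height
  assumed equal to width)
* cylinder  V = area * height                    (scanner convention)
* ellipsoid V = (pi/6) * length * width * height (scanner convention with
  measured height; reduces to the spheroid form when height == width)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._errors import MeasurementError
from .ca import GrowthCurve, Lattice

_CORNER_OFFSETS = np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)])


@dataclass(frozen=True)
class LinearMeasurements:
    """Calliper-style linear extents of one tumour, all in mm / mm^2."""

    length: float
    width: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height, self.area) < 0:
            raise ValueError("measurements must be non-negative")
        if self.width > self.length + 1e-9:
            raise ValueError("width must not exceed length")


def _footprint_corners(footprint: np.ndarray) -> np.ndarray:
    """Outer corner points (in voxel units) of all occupied footprint pixels."""
    px = np.argwhere(footprint).astype(np.float64)
    corners = (px[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 2)
    return np.unique(corners, axis=0)


def _hull_points(points: np.ndarray) -> np.ndarray:
    if points.shape[0] <= 4:
        return points
    try:
        from scipy.spatial import ConvexHull

        return points[ConvexHull(points).vertices]
    except Exception:
        return points


def feret_extents(
    footprint: np.ndarray, angle_step_deg: float = 1.0
) -> tuple[float, float, float]:
    """(length, width, angle) of a boolean footprint in voxel units.

    Length is the max directional extent over angles [0, 180) sampled at
    ``angle_step_deg``; width is the extent at the perpendicular angle.
    """
    pts = _hull_points(_footprint_corners(footprint))
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (a, 2)
    proj = pts @ dirs.T  # (p, a)
    extents = proj.max(axis=0) - proj.min(axis=0)
    i = int(np.argmax(extents))
    length = float(extents[i])
    perp = np.array([-dirs[i, 1], dirs[i, 0]])
    pproj = pts @ perp
    width = float(pproj.max() - pproj.min())
    return length, width, float(np.rad2deg(angles[i]))


def simulated_calliper(lattice: Lattice, angle_step_deg: float = 1.0) -> LinearMeasurements:
    """Measure a voxel tumour as a calliper would: footprint feret length/width,
    plus vertical height and footprint area."""
    occ = lattice.occupied
    if not occ.any():
        raise MeasurementError("cannot measure an empty lattice")
    footprint = occ.any(axis=2)
    length_vox, width_vox, _ = feret_extents(footprint, angle_step_deg)
    zmax = int(np.max(np.nonzero(occ.any(axis=(0, 1)))[0]))
    e = lattice.voxel_edge
    return LinearMeasurements(
        length=length_vox * e,
        width=min(width_vox, length_vox) * e,
        height=(zmax + 1) * e,
        area=float(footprint.sum()) * e * e,
    )


def spheroid_volume(length: float, width: float) -> float:
    """(pi/6) * length * width^2; swaps the arguments (with a warning) if
    width > length."""
    if length < 0 or width < 0:
        raise ValueError("length and width must be non-negative")
    if width > length:
        warnings.warn("width exceeded length; arguments swapped", stacklevel=2)
        length, width = width, length
    return math.pi / 6.0 * length * width * width


def cylindrical_volume(area: float, height: float) -> float:
    """area * height."""
    if area < 0 or height < 0:
        raise ValueError("area and height must be non-negative")
    return area * height


def ellipsoid_volume(length: float, width: float, height: float) -> float:
    """(pi/6) * length * width * height."""
    if length < 0 or width < 0 or height < 0:
        raise ValueError("all dimensions must be non-negative")
    return math.pi / 6.0 * length * width * height


def volume_from_measurements(m: LinearMeasurements, method: str) -> float:
    if method == "SC":
        return spheroid_volume(m.length, m.width)
    if method == "CYL":
        return cylindrical_volume(m.area, m.height)
    if method == "ELL":
        return ellipsoid_volume(m.length, m.width, m.height)
    raise ValueError(f"unknown volume method {method!r}; expected SC, CYL or ELL")


def measure_curve(
    snapshots: Sequence[Lattice],
    method: str = "SC",
    arm: str = "control",
    angle_step_deg: float = 1.0,
) -> GrowthCurve:
    """Apply the virtual calliper to every snapshot and convert to volume.

    Empty snapshots yield volume 0 and are recorded in ``empty_days``.
    """
    if len(snapshots) == 0:
        raise MeasurementError("empty snapshot sequence")
    if method not in ("SC", "CYL", "ELL"):
        raise ValueError(f"unknown volume method {method!r}")
    volumes = np.zeros(len(snapshots))
    empty_days: list[int] = []
    for day, lat in enumerate(snapshots):
        if lat.cell_count() == 0:
            empty_days.append(day)
            continue
        m = simulated_calliper(lat, angle_step_deg)
        volumes[day] = volume_from_measurements(m, method)
    return GrowthCurve(
        days=np.arange(len(snapshots)),
        volume_mm3=volumes,
        method=method,
        arm=arm,
        empty_days=tuple(empty_days),
    )
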