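"""Contour geometry: polylines, arc-length resampling and wall-thickness sampling.

Long-axis (LAX) wall contours are *open* 2-D polylines in millimetres running
from one basal endpoint, around the apex, to the contralateral basal endpoint.
Thickness is sampled at ``n_samples`` (default 100) arc-length-uniform stations
on the endocardial contour; each sample is the minimal Euclidean distance from
the station to the epicardial polyline.  All coordinates are image coordinates
(y increases downward); "counter-clockwise" traversal is fixed by the stored
vertex order of the endocardial contour, whose first point is the starting
basal endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .errors import InvalidContourError, InvalidPairError, InvalidSequenceError

PLANES = ("A2C", "A3C", "A4C")

#: Default number of thickness stations per plane.
N_SAMPLES_DEFAULT = 100


@dataclass(frozen=True)
class ContourPolyline:
    """An ordered open (or closed) 2-D polyline in millimetres.

    Parameters
    ----------
    points : (n, 2) array
        Vertex coordinates in mm.
    closed : bool
        Whether the last vertex connects back to the first.  LAX wall
        contours are open.
    """

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidContourError(f"points must be (n, 2), got shape {pts.shape}")
        if pts.shape[0] < 3:
            raise InvalidContourError(f"contour needs >= 3 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise InvalidContourError("contour contains non-finite coordinates")
        seg = np.diff(pts, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seglen == 0.0):
            i = int(np.argmax(seglen == 0.0))
            raise InvalidContourError(f"identical consecutive points at index {i}")
        if float(seglen.sum()) <= 0.0:
            raise InvalidContourError("contour has zero arc length")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def arc_length(self) -> float:
        """Total length in mm (including the closing segment if closed)."""
        seg = np.diff(self.points, axis=0)
        total = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        if self.closed:
            total += float(np.hypot(*(self.points[0] - self.points[-1])))
        return total

    def cumulative_arc(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        seg = np.diff(self.points, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0)) -> "ContourPolyline":
        """Return a rigidly moved copy (rotation about the origin, then shift)."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return replace(self, points=self.points @ rot.T + np.asarray(translation, float))


@dataclass(frozen=True)
class LAXContourPair:
    """One plane's endocardial + epicardial contour pair with study metadata."""

    plane_id: str
    endo: ContourPolyline
    epi: ContourPolyline
    apex_marked: bool = False
    subject_id: str = ""
    reader_id: str = ""
    phase: str = ""

    def __post_init__(self) -> None:
        if self.plane_id not in PLANES:
            raise InvalidPairError(f"unknown plane id {self.plane_id!r}; expected one of {PLANES}")
        if self.endo.closed or self.epi.closed:
            raise InvalidPairError("LAX wall contours must be open curves")
        if self.endo.arc_length > 1.5 * self.epi.arc_length:
            raise InvalidPairError(
                f"endo arc length {self.endo.arc_length:.1f} mm exceeds "
                f"1.5 x epi arc length {self.epi.arc_length:.1f} mm"
            )


@dataclass(frozen=True)
class DistanceSequence:
    """Ordered wall-thickness samples along one plane's base->apex->base path.

    The central input of the segmentation algorithm: ``values[i]`` is the wall
    thickness in mm at the i-th of ``n_samples`` arc-length-uniform stations.
    """

    plane_id: str
    values: np.ndarray
    start_side: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise InvalidSequenceError("values must be one-dimensional")
        if vals.size < 12:
            raise InvalidSequenceError(
                f"need >= 12 samples (apex run + 6 nonempty groups), got {vals.size}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidSequenceError("values contain non-finite entries")
        if np.any(vals < 0):
            raise InvalidSequenceError("thickness values must be >= 0")
        if self.plane_id not in PLANES:
            raise InvalidSequenceError(f"unknown plane id {self.plane_id!r}")
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)


def resample_polyline(contour: ContourPolyline, n: int) -> ContourPolyline:
    """Resample a polyline to ``n`` points uniformly spaced in arc length.

    The first and last original points are preserved exactly.
    """
    if not isinstance(n, (int, np.integer)) or n < 2:
        raise ValueError(f"n must be an integer >= 2, got {n!r}")
    s = contour.cumulative_arc()
    targets = np.linspace(0.0, s[-1], int(n))
    x = np.interp(targets, s, contour.points[:, 0])
    y = np.interp(targets, s, contour.points[:, 1])
    pts = np.column_stack([x, y])
    pts[0] = contour.points[0]
    pts[-1] = contour.points[-1]
    return ContourPolyline(points=pts, closed=False)


def point_to_polyline_distances(points: np.ndarray, polyline: ContourPolyline) -> np.ndarray:
    """Minimal Euclidean distance from each query point to a polyline (mm)."""
    line = shapely.LineString(polyline.points)
    return shapely.distance(shapely.points(np.asarray(points, float)), line)


def sample_wall_thickness(pair: LAXContourPair, n_samples: int = N_SAMPLES_DEFAULT,
                          start_side: str = "") -> DistanceSequence:
    """Sample endo-to-epi wall thickness at ``n_samples`` stations.

    The endocardial contour is resampled to ``n_samples`` arc-length-uniform
    stations ordered from its first basal endpoint, through the apex, to the
    contralateral basal endpoint.  Each value is the minimal distance from the
    station to the epicardial polyline (point-to-segment over all segments) —
    exact on concentric annuli and robust to vertex density.
    """
    if pair.epi.n_points < 2:
        raise InvalidContourError("epicardial contour needs >= 2 points")
    stations = resample_polyline(pair.endo, n_samples)
    values = point_to_polyline_distances(stations.points, pair.epi)
    return DistanceSequence(
        plane_id=pair.plane_id,
        values=values,
        start_side=start_side,
        metadata={"subject_id": pair.subject_id, "reader_id": pair.reader_id,
                  "method": "contour_sampled", "n_samples": int(n_samples)},
    )
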