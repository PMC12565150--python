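"""Anatomical segmentation of wall-distance sequences.

The algorithm (per plane):

1. **Apex detection** — the study is apex-marked: the endocardial contour was
   collapsed onto the epicardial contour over ~10 mm at the apex, so the
   distance sequence dips close to 0 there.  The longest contiguous run of
   samples below ``epsilon_mm`` is the apex landmark (segment 17, excluded
   from all thickness averages).
2. **Equal-thirds splitting** — the samples before and after the run (the two
   base->apex wall paths) are each divided into three equal-count groups:
   basal, mid, apical.  Boundaries are the proportional floor rule
   ``floor(k*m/3)`` applied in base->apex orientation on both sides, so
   remainder samples fall toward the apex symmetrically.
3. **AHA-16 mapping** — the six plane-side thirds of the three LAX planes are
   assigned to the 16 segments of the AHA model (segment 17 dropped).  The
   apical septal (S14) and apical lateral (S16) segments are seen by both the
   3- and 4-chamber planes and take the unweighted mean of the two planes'
   apical third means.
4. **Aggregates** — unweighted means over basal (S1-S6), mid (S7-S12) and
   apical (S13-S16) segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np

from .errors import (
    ApexAtBoundaryError,
    ApexNotFoundError,
    CorruptSequenceError,
    IncompleteMapError,
    IncompleteStudyError,
    InvalidConventionError,
    SideTooShortError,
)
from .geometry import (
    PLANES,
    N_SAMPLES_DEFAULT,
    DistanceSequence,
    LAXContourPair,
    sample_wall_thickness,
)

SEGMENTS = tuple(f"S{i}" for i in range(1, 17))
BASAL_SEGMENTS = tuple(f"S{i}" for i in range(1, 7))
MID_SEGMENTS = tuple(f"S{i}" for i in range(7, 13))
APICAL_SEGMENTS = tuple(f"S{i}" for i in range(13, 17))

THIRDS = ("basal", "mid", "apical")

#: Default apex-run threshold in mm ("close to zero"); configurable.
EPSILON_MM_DEFAULT = 0.5

#: Expected apex-run length band (samples); outside it a warning is emitted.
APEX_RUN_WARN_BAND = (2, 15)


class ApexRunLengthWarning(UserWarning):
    """The apex run is shorter/longer than the expected 2-15 sample band."""


# ---------------------------------------------------------------------------
# Plane-side -> wall -> segment convention


@dataclass(frozen=True)
class Convention:
    """Maps each plane's two wall sides to anatomical walls, and each wall's
    basal/mid/apical thirds to AHA segments.

    ``plane_sides[plane] = (wall of the side sampled first, wall sampled last)``.
    ``wall_segments[wall] = (basal seg, mid seg, apical seg)``; the apical
    entries of the two septal-ish walls are both S14 and of the two lateral-ish
    walls both S16 (two-plane averaging).
    """

    plane_sides: Mapping[str, tuple]
    wall_segments: Mapping[str, tuple]

    def __post_init__(self) -> None:
        seen: dict = {}
        for plane in PLANES:
            if plane not in self.plane_sides:
                raise InvalidConventionError(f"plane {plane} missing from convention")
            for wall in self.plane_sides[plane]:
                if wall not in self.wall_segments:
                    raise InvalidConventionError(f"wall {wall!r} has no segment mapping")
                for third, seg in zip(THIRDS, self.wall_segments[wall]):
                    seen.setdefault(seg, []).append((plane, wall, third))
        if set(seen) != set(SEGMENTS):
            missing = sorted(set(SEGMENTS) - set(seen))
            extra = sorted(set(seen) - set(SEGMENTS))
            raise InvalidConventionError(
                f"convention must cover S1..S16; missing={missing} extra={extra}"
            )
        for seg, sources in seen.items():
            want = 2 if seg in ("S14", "S16") else 1
            if len(sources) != want:
                raise InvalidConventionError(
                    f"{seg} has {len(sources)} contributing plane-sides, expected {want}"
                )
        object.__setattr__(self, "_sources", seen)

    def sources(self, seg: str):
        """(plane, wall, third) tuples contributing to a segment."""
        return list(self._sources[seg])


def default_convention() -> Convention:
    """The standard LAX assignment: 2-chamber shows the anterior and inferior
    walls, 3-chamber the anteroseptal and inferolateral, 4-chamber the
    inferoseptal and anterolateral walls."""
    return Convention(
        plane_sides={
            "A2C": ("anterior", "inferior"),
            "A3C": ("anteroseptal", "inferolateral"),
            "A4C": ("inferoseptal", "anterolateral"),
        },
        wall_segments={
            "anterior": ("S1", "S7", "S13"),
            "inferior": ("S4", "S10", "S15"),
            "anteroseptal": ("S2", "S8", "S14"),
            "inferolateral": ("S5", "S11", "S16"),
            "inferoseptal": ("S3", "S9", "S14"),
            "anterolateral": ("S6", "S12", "S16"),
        },
    )


# ---------------------------------------------------------------------------
# Stage 1: apex detection


@dataclass(frozen=True)
class ApexDetection:
    """The near-zero run marking the apex (segment 17) in one sequence."""

    run_start: int
    run_end: int  # half-open
    apex_index: int
    epsilon_mm: float

    def __post_init__(self) -> None:
        if not (0 <= self.run_start < self.run_end):
            raise ValueError("require 0 <= run_start < run_end")
        if not (self.run_start <= self.apex_index < self.run_end):
            raise ValueError("apex_index must lie inside the run")

    @property
    def run_length(self) -> int:
        return self.run_end - self.run_start


def _maximal_runs(mask: np.ndarray):
    """(start, end) half-open index pairs of maximal True runs."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_apex(seq: DistanceSequence, epsilon_mm: float = EPSILON_MM_DEFAULT) -> ApexDetection:
    """Find the apex-marking run: the longest contiguous run of values below
    ``epsilon_mm``.

    Ties between equal-length runs are broken toward the run whose centre is
    nearest the sequence midpoint (the apex should sit mid-path), then toward
    the earlier run.  The apex index is the lower-middle sample of the run.
    """
    if epsilon_mm <= 0:
        raise ValueError("epsilon_mm must be positive")
    n = seq.n_samples
    runs = _maximal_runs(seq.values < epsilon_mm)
    if not runs:
        raise ApexNotFoundError(
            f"no sample below {epsilon_mm} mm: sequence does not look apex-marked"
        )
    mid = (n - 1) / 2.0

    def key(run):
        start, end = run
        centre = (start + end - 1) / 2.0
        return (-(end - start), abs(centre - mid), start)

    start, end = min(runs, key=key)
    if start == 0 or end == n:
        raise ApexAtBoundaryError(
            f"apex run [{start}, {end}) touches the sequence boundary; "
            "expected a base->apex->base path"
        )
    length = end - start
    if length > 0.3 * n:
        raise CorruptSequenceError(
            f"apex run of {length} samples exceeds 30% of the sequence ({n})"
        )
    lo, hi = APEX_RUN_WARN_BAND
    if not (lo <= length <= hi):
        warnings.warn(
            f"apex run length {length} outside the expected [{lo}, {hi}] band "
            "(the marking window usually yields roughly 4-8 near-zero samples)",
            ApexRunLengthWarning,
            stacklevel=2,
        )
    apex_index = (start + end - 1) // 2
    return ApexDetection(run_start=start, run_end=end, apex_index=apex_index,
                         epsilon_mm=float(epsilon_mm))


# ---------------------------------------------------------------------------
# Stage 2: equal thirds


@dataclass(frozen=True)
class ThirdGroup:
    """One basal/mid/apical group of samples on one side of the apex."""

    label: str          # basal | mid | apical
    start: int          # half-open sample index range
    stop: int
    count: int
    mean_mm: float


@dataclass(frozen=True)
class PlaneThirds:
    """The six thirds of one plane: three per side of the apex run.

    Groups are keyed by anatomical label; together with the apex run the six
    index ranges partition ``[0, n_samples)`` exactly.
    """

    plane_id: str
    side_pre: Mapping[str, ThirdGroup]   # side sampled before the apex
    side_post: Mapping[str, ThirdGroup]  # side sampled after the apex
    apex: ApexDetection
    n_samples: int


def _floor_boundaries(m: int):
    return [(k * m) // 3 for k in range(4)]


def split_thirds(seq: DistanceSequence, apex: ApexDetection) -> PlaneThirds:
    """Split the samples outside the apex run into basal/mid/apical thirds.

    Both sides use the proportional floor boundaries ``floor(k*m/3)`` in
    base->apex orientation, so each side's group sizes differ by at most one
    and any remainder samples fall toward the apex.  Apex-run samples belong
    to no group (segment 17 is excluded).
    """
    n = seq.n_samples
    if apex.run_end > n:
        raise ValueError("apex detection does not fit the sequence")
    vals = seq.values

    def group(label, start, stop):
        return ThirdGroup(label=label, start=int(start), stop=int(stop),
                          count=int(stop - start), mean_mm=float(vals[start:stop].mean()))

    m_pre = apex.run_start
    m_post = n - apex.run_end
    for side, m in (("pre", m_pre), ("post", m_post)):
        if m < 3:
            raise SideTooShortError(
                f"{side}-apex side has {m} samples; need >= 3 to form thirds"
            )

    b = _floor_boundaries(m_pre)  # base at index 0 -> apex
    side_pre = {
        "basal": group("basal", b[0], b[1]),
        "mid": group("mid", b[1], b[2]),
        "apical": group("apical", b[2], b[3]),
    }
    # post side runs apex -> base; mirror the rule so it is base -> apex too
    c = _floor_boundaries(m_post)
    side_post = {
        "basal": group("basal", n - c[1], n),
        "mid": group("mid", n - c[2], n - c[1]),
        "apical": group("apical", apex.run_end, n - c[2]),
    }
    return PlaneThirds(plane_id=seq.plane_id, side_pre=side_pre, side_post=side_post,
                       apex=apex, n_samples=n)


# ---------------------------------------------------------------------------
# Stages 3-4: AHA-16 mapping and aggregates


@dataclass(frozen=True)
class SegmentalMap16:
    """16 AHA segment thickness values (mm) with provenance and aggregates."""

    seg_values: Mapping[str, float]
    seg_counts: Mapping[str, int]
    s_avg_bas: float
    s_avg_mid: float
    s_avg_api: float
    provenance: Mapping[str, list] = field(default_factory=dict)
    apex_audits: Mapping[str, ApexDetection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SEGMENTS if s not in self.seg_values]
        if missing:
            raise IncompleteMapError(f"missing segments: {missing}")

    def values_array(self) -> np.ndarray:
        return np.array([self.seg_values[s] for s in SEGMENTS])


def map_to_aha16(thirds_by_plane: Mapping[str, PlaneThirds],
                 convention: Convention | None = None) -> SegmentalMap16:
    """Assign the 18 plane-side thirds (6 per plane) to the 16 AHA segments.

    Every segment except S14/S16 takes its single plane-side-third mean; S14
    (apical septal) and S16 (apical lateral) take the unweighted mean of the
    3- and 4-chamber apical thirds of the corresponding walls.
    """
    convention = convention or default_convention()
    missing = [p for p in PLANES if p not in thirds_by_plane]
    if missing:
        raise IncompleteStudyError(f"missing planes: {missing}")

    # (plane, wall) -> side groups
    wall_groups: dict = {}
    for plane in PLANES:
        thirds = thirds_by_plane[plane]
        wall_pre, wall_post = convention.plane_sides[plane]
        wall_groups[(plane, wall_pre)] = thirds.side_pre
        wall_groups[(plane, wall_post)] = thirds.side_post

    seg_values: dict = {}
    seg_counts: dict = {}
    provenance: dict = {}
    apex_audits = {p: thirds_by_plane[p].apex for p in PLANES}
    for seg in SEGMENTS:
        sources = convention.sources(seg)
        means, counts = [], 0
        for plane, wall, third in sources:
            g = wall_groups[(plane, wall)][third]
            means.append(g.mean_mm)
            counts += g.count
        seg_values[seg] = float(np.mean(means))  # unweighted across planes
        seg_counts[seg] = counts
        provenance[seg] = sources
    m = SegmentalMap16(seg_values=seg_values, seg_counts=seg_counts,
                       s_avg_bas=0.0, s_avg_mid=0.0, s_avg_api=0.0,
                       provenance=provenance, apex_audits=apex_audits)
    return aggregate(m)


def aggregate(map16: SegmentalMap16) -> SegmentalMap16:
    """Recompute the basal/mid/apical aggregates as unweighted segment means."""
    v = map16.seg_values
    return replace(
        map16,
        s_avg_bas=float(np.mean([v[s] for s in BASAL_SEGMENTS])),
        s_avg_mid=float(np.mean([v[s] for s in MID_SEGMENTS])),
        s_avg_api=float(np.mean([v[s] for s in APICAL_SEGMENTS])),
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the measurement pipeline."""

    n_samples: int = N_SAMPLES_DEFAULT
    epsilon_mm: float = EPSILON_MM_DEFAULT
    convention: Convention | None = None


StudyInput = Mapping[str, Union[LAXContourPair, DistanceSequence]]


def run_pipeline(study: StudyInput, config: PipelineConfig | None = None) -> SegmentalMap16:
    """Full chain: (sample ->) detect apex -> split thirds -> map -> aggregate.

    ``study`` maps each of A2C/A3C/A4C to either a contour pair (sampled at
    ``config.n_samples`` stations) or a ready-made distance sequence (e.g. a
    parsed CSV export).  Per-plane apex detections are retained on the result
    for audit.
    """
    config = config or PipelineConfig()
    convention = config.convention or default_convention()
    missing = [p for p in PLANES if p not in study]
    if missing:
        raise IncompleteStudyError(f"study is missing planes: {missing}")

    thirds_by_plane: dict = {}
    for plane in PLANES:
        item = study[plane]
        try:
            if isinstance(item, LAXContourPair):
                seq = sample_wall_thickness(item, config.n_samples,
                                            start_side=convention.plane_sides[plane][0])
            else:
                seq = item
            apex = detect_apex(seq, config.epsilon_mm)
            thirds_by_plane[plane] = split_thirds(seq, apex)
        except (ApexNotFoundError, ApexAtBoundaryError, CorruptSequenceError,
                SideTooShortError) as exc:
            raise type(exc)(f"[{plane}] {exc}") from exc
    return map_to_aha16(thirds_by_plane, convention)
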