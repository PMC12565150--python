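"""Synthetic long-axis LV phantoms and observer simulators.

The phantom emulates what the measurement stage sees in a marked clinical
study, with no patient data:

* **Epicardial contour** — a half-ellipse (semi-axes ``a`` across, ``b``
  base-to-apex, mm), traversed base -> apex -> base, vertices uniform in arc
  length.
* **Endocardial contour** — the epicardium offset inward along local normals
  by a region-wise thickness profile (six plane-side thirds per plane,
  collapsible to a 16-segment truth vector).
* **Apex marking** — within an ``apex_window_mm`` arc window centred on the
  apex the endocardial vertices are snapped onto the (noisy) epicardial
  contour, so sampled distances dip to ~0 mm there: the detectable landmark.
* **Contour noise** — arc-length-correlated Gaussian jitter (correlation
  length ~5 mm) applied to both contours, emulating tracing deviations of a
  human-corrected automatic contour.  White per-vertex jitter is deliberately
  not used: it makes minimum-distance sampling biased low against a jagged
  polyline and does not resemble tracing error.

A marked endocardial contour must physically travel ~tau mm of arc to reach
the epicardium at the window edge, so a handful of samples on those
transition segments carry intermediate distances; they land in the apical
groups and bias apical segment means low by a few tenths of a millimetre.
Real marked exports share this property.  The sequence-level generator
(:func:`generate_sequence_study`) emulates the idealised CSV export with no
transition shoulders and recovers arbitrary profiles exactly.

Two observer behaviours are modelled: a *single-caliper* reader who eyeballs
one measurement per segment at a subjectively chosen position, and a
*contour-averaged* reader whose value is the full pipeline output from an
independently re-traced contour pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidSpecError
from .geometry import PLANES, ContourPolyline, DistanceSequence, LAXContourPair
from .segmentation import (
    SEGMENTS,
    THIRDS,
    Convention,
    PipelineConfig,
    default_convention,
    run_pipeline,
)

GROUP_TEMPLATES = {
    # basal / mid / apical target thickness (mm); scene-setting values in the
    # range reported for healthy and excessively trabeculated (thin-apex) LVs
    "HEALTHY-like": (6.5, 5.9, 5.4),
    "LVET-like": (6.4, 5.7, 4.75),
}

#: Width of the zero-thickness apex-marking window (mm).
APEX_WINDOW_MM_DEFAULT = 10.0


# ---------------------------------------------------------------------------
# Thickness profiles


def profile_from_truth16(truth: Mapping[str, float],
                         convention: Convention | None = None) -> dict:
    """Expand a 16-segment truth vector to the per-plane wall-third profile.

    Returns ``{plane: {"pre": (bas, mid, api), "post": (bas, mid, api)}}``;
    the shared apical segments (S14, S16) feed both contributing planes.
    """
    convention = convention or default_convention()
    profile: dict = {}
    for plane in PLANES:
        sides = {}
        for key, wall in zip(("pre", "post"), convention.plane_sides[plane]):
            segs = convention.wall_segments[wall]
            sides[key] = tuple(float(truth[s]) for s in segs)
        profile[plane] = sides
    return profile


def truth16_from_profile(profile: Mapping[str, Mapping[str, tuple]],
                         convention: Convention | None = None) -> dict:
    """Collapse a wall-third profile back to the 16-segment truth vector
    (S14/S16 as the mean of their two contributing planes)."""
    convention = convention or default_convention()
    acc: dict = {s: [] for s in SEGMENTS}
    for plane in PLANES:
        for key, wall in zip(("pre", "post"), convention.plane_sides[plane]):
            for third_idx, seg in enumerate(convention.wall_segments[wall]):
                acc[seg].append(float(profile[plane][key][third_idx]))
    return {s: float(np.mean(v)) for s, v in acc.items()}


def constant_profile(thickness_mm: float) -> dict:
    """A profile with the same thickness everywhere."""
    triple = (float(thickness_mm),) * 3
    return {plane: {"pre": triple, "post": triple} for plane in PLANES}


def wall_profile_fn(triple: Sequence[float]) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous thickness along one wall as a function of position in [0, 1]
    (0 = base, 1 = apex-window edge): piecewise-linear through the three third
    values placed at the third centres, flat beyond the outer centres."""
    knots = np.array([1 / 6, 3 / 6, 5 / 6])
    vals = np.asarray(triple, dtype=float)

    def f(u):
        return np.interp(np.asarray(u, dtype=float), knots, vals)

    return f


def _piecewise_third(u: np.ndarray, triple: Sequence[float]) -> np.ndarray:
    """Region-wise constant thickness: u in [0,1) base->apex, thirds equal."""
    idx = np.minimum((np.asarray(u) * 3).astype(int), 2)
    return np.asarray(triple, dtype=float)[idx]


# ---------------------------------------------------------------------------
# Phantom spec and contour generation


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic LV long-axis study."""

    epi_semi_axes: tuple = (30.0, 75.0)
    thickness_profile: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: constant_profile(6.0))
    apex_window_mm: float = APEX_WINDOW_MM_DEFAULT
    contour_noise_sd_mm: float = 0.0
    noise_corr_mm: float = 2.0
    n_vertices: int = 512
    seed: int | None = None

    def __post_init__(self) -> None:
        a, b = self.epi_semi_axes
        if a <= 0 or b <= 0:
            raise InvalidSpecError("semi-axes must be positive")
        if self.apex_window_mm < 0:
            raise InvalidSpecError("apex_window_mm must be >= 0")
        if self.n_vertices < 64:
            raise InvalidSpecError("n_vertices must be >= 64")
        if self.contour_noise_sd_mm < 0:
            raise InvalidSpecError("contour_noise_sd_mm must be >= 0")
        # inward offsets must stay below the reach of the curve: the minimal
        # radius of curvature of the half-ellipse is a^2/b (at the apex)
        limit = min(a * a / b, min(a, b) / 2.0)
        tmax = max(max(sides[k]) for sides in self.thickness_profile.values()
                   for k in ("pre", "post"))
        tmin = min(min(sides[k]) for sides in self.thickness_profile.values()
                   for k in ("pre", "post"))
        if tmin <= 0:
            raise InvalidSpecError("all thicknesses must be > 0")
        if tmax >= limit:
            raise InvalidSpecError(
                f"max thickness {tmax:.1f} mm exceeds the curvature-safe "
                f"offset limit {limit:.1f} mm for semi-axes {a}, {b}"
            )


def correlated_noise(n: int, sd_mm: float, corr_mm: float, spacing_mm: float,
                     rng: np.random.Generator) -> np.ndarray:
    """(n, 2) Gaussian jitter with arc-length correlation and exact marginal sd."""
    if sd_mm == 0.0:
        return np.zeros((n, 2))
    white = rng.standard_normal((n, 2))
    sigma_v = max(corr_mm / spacing_mm, 1e-9)
    impulse = np.zeros(2 * int(4 * sigma_v) + 9)
    impulse[impulse.size // 2] = 1.0
    kernel = gaussian_filter1d(impulse, sigma_v, mode="constant")
    scale = float(np.sqrt(np.sum(kernel ** 2)))
    # periodic smoothing keeps the field stationary: no variance inflation at
    # the curve ends (tracing error is not special at the basal endpoints)
    smooth = gaussian_filter1d(white, sigma_v, axis=0, mode="wrap")
    return smooth * (sd_mm / scale)


def _half_ellipse(a: float, b: float, n_vertices: int):
    """Arc-length-uniform vertices of the half-ellipse t in [0, pi], with the
    parameter values and cumulative arc length."""
    t_dense = np.linspace(0.0, np.pi, 40 * n_vertices)
    pts = np.column_stack([a * np.cos(t_dense), b * np.sin(t_dense)])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    s_targets = np.linspace(0.0, s_dense[-1], n_vertices)
    t = np.interp(s_targets, s_dense, t_dense)
    points = np.column_stack([a * np.cos(t), b * np.sin(t)])
    return points, t, s_targets, float(s_dense[-1])


def _thickness_along_arc(s: np.ndarray, total: float, window: float,
                         sides: Mapping[str, tuple]) -> np.ndarray:
    """Piecewise-constant thickness profile along epicardial arc length;
    zero inside the apex-marking window."""
    tau = np.empty_like(s)
    half = total / 2.0
    pre_len = half - window / 2.0
    in_win = np.abs(s - half) <= window / 2.0
    pre = s < half - window / 2.0
    post = s > half + window / 2.0
    tau[pre] = _piecewise_third(s[pre] / pre_len, sides["pre"])
    tau[post] = _piecewise_third((total - s[post]) / pre_len, sides["post"])
    tau[in_win] = 0.0
    return tau


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> dict:
    """Generate the three-plane contour study described by ``spec``.

    Returns ``{plane: LAXContourPair}``.  Identical spec + seed gives
    identical output.
    """
    seed = spec.seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(len(PLANES))
    a, b = spec.epi_semi_axes
    study = {}
    for plane, ss in zip(PLANES, child):
        rng = np.random.default_rng(ss)
        epi_pts, t, s, total = _half_ellipse(a, b, spec.n_vertices)
        spacing = total / (spec.n_vertices - 1)
        tau = _thickness_along_arc(s, total, spec.apex_window_mm,
                                   spec.thickness_profile[plane])
        # unit inward normal of the ellipse at parameter t
        grad = np.column_stack([np.cos(t) / a, np.sin(t) / b])
        n_in = -grad / np.linalg.norm(grad, axis=1, keepdims=True)
        endo_pts = epi_pts + n_in * tau[:, None]

        epi_noisy = epi_pts + correlated_noise(spec.n_vertices, spec.contour_noise_sd_mm,
                                               spec.noise_corr_mm, spacing, rng)
        endo_noisy = endo_pts + correlated_noise(spec.n_vertices, spec.contour_noise_sd_mm,
                                                 spec.noise_corr_mm, spacing, rng)
        # apex marking: the reader aligns the endo onto the traced epi, so the
        # marked window coincides with the *noisy* epicardial contour
        in_win = np.abs(s - total / 2.0) <= spec.apex_window_mm / 2.0
        endo_noisy[in_win] = epi_noisy[in_win]

        study[plane] = LAXContourPair(
            plane_id=plane,
            endo=ContourPolyline(endo_noisy),
            epi=ContourPolyline(epi_noisy),
            apex_marked=spec.apex_window_mm > 0,
        )
    return study


# ---------------------------------------------------------------------------
# Sequence-level phantom (idealised distance-export emulation)


def generate_sequence_study(profile: Mapping[str, Mapping[str, tuple]],
                            n_samples: int = 100,
                            apex_run_length: int = 6,
                            noise_sd_mm: float = 0.0,
                            seed: int | None = None) -> dict:
    """Emulate the 100-value distance export directly, with no contour stage.

    Values are the region-wise profile thickness at each station, a centred
    near-zero run of ``apex_run_length`` samples marking the apex, and
    optional i.i.d. Gaussian measurement noise.  Region boundaries follow the
    package's floor(k*m/3) equal-thirds convention.
    """
    rng = np.random.default_rng(seed)
    run_start = (n_samples - apex_run_length) // 2
    run_end = run_start + apex_run_length
    study = {}
    for plane in PLANES:
        sides = profile[plane]
        values = np.empty(n_samples)
        values[run_start:run_end] = 0.1  # "close to zero"
        # regions follow the equal-thirds floor-boundary convention, applied
        # base->apex on both sides (mirrored on the post side)
        b = [(k * run_start) // 3 for k in range(4)]
        m_post = n_samples - run_end
        c = [(k * m_post) // 3 for k in range(4)]
        for k in range(3):
            values[b[k]:b[k + 1]] = sides["pre"][k]
            values[n_samples - c[k + 1]:n_samples - c[k]] = sides["post"][k]
        if noise_sd_mm > 0:
            values = values + rng.normal(0.0, noise_sd_mm, n_samples)
            values = np.clip(values, 0.0, None)
        study[plane] = DistanceSequence(plane_id=plane, values=values,
                                        metadata={"method": "sequence_phantom"})
    return study


# ---------------------------------------------------------------------------
# Cohorts and observers


@dataclass(frozen=True)
class SubjectTruth:
    subject_id: str
    group: str
    sex: str
    truth16: Mapping[str, float]


def generate_cohort(group: str, n_subjects: int, seed: int | None = None) -> list:
    """Draw per-subject 16-segment truth vectors around a group template.

    Subject-level offset sd 0.4 mm plus per-segment sd 0.3 mm (between-subject
    sd ~0.5 mm per segment).  Sexes alternate for stratified table building.
    """
    if group not in GROUP_TEMPLATES:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(GROUP_TEMPLATES)}")
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    bas, mid, api = GROUP_TEMPLATES[group]
    template = {s: bas for s in SEGMENTS[:6]}
    template.update({s: mid for s in SEGMENTS[6:12]})
    template.update({s: api for s in SEGMENTS[12:]})
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        offset = rng.normal(0.0, 0.4)
        truth = {s: max(2.0, template[s] + offset + rng.normal(0.0, 0.3))
                 for s in SEGMENTS}
        subjects.append(SubjectTruth(
            subject_id=f"{group.split('-')[0]}{i + 1:03d}",
            group=group, sex="F" if i % 2 else "M", truth16=truth))
    return subjects


@dataclass(frozen=True)
class ObserverModel:
    """A reader behaviour.

    ``single_caliper``: one eyeballed measurement per segment, uniformly
    placed within a ``placement_jitter`` fraction of the segment span, plus
    Gaussian measurement noise — the conventional manual technique, which has
    no standard within-segment measurement point.

    ``contour_averaged``: the reader independently re-traces the contours
    (correlated jitter of ``contour_noise_sd_mm``) and reports the full
    pipeline output — the automated technique.
    """

    kind: str
    placement_jitter: float = 1.0
    measurement_noise_sd_mm: float = 0.0
    contour_noise_sd_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single_caliper", "contour_averaged"):
            raise ValueError(f"unknown observer kind {self.kind!r}")
        if not (0.0 <= self.placement_jitter <= 1.0):
            raise ValueError("placement_jitter must be in [0, 1]")
        if self.measurement_noise_sd_mm < 0 or self.contour_noise_sd_mm < 0:
            raise ValueError("noise parameters must be >= 0")


def default_single_caliper() -> ObserverModel:
    """Default manual-reader contrast setting: full-segment placement jitter,
    0.4 mm caliper noise."""
    return ObserverModel(kind="single_caliper", placement_jitter=1.0,
                         measurement_noise_sd_mm=0.4)


def default_contour_averaged() -> ObserverModel:
    """Default automated-reader contrast setting: 0.3 mm contour re-tracing
    jitter, pipeline-averaged output."""
    return ObserverModel(kind="contour_averaged", contour_noise_sd_mm=0.3)


def _measure_single_caliper(truth16, model: ObserverModel, rng,
                            convention: Convention) -> dict:
    profile = profile_from_truth16(truth16, convention)
    walls = {}
    for plane in PLANES:
        for key, wall in zip(("pre", "post"), convention.plane_sides[plane]):
            walls[(plane, wall)] = wall_profile_fn(profile[plane][key])
    out = {}
    for seg in SEGMENTS:
        draws = []
        for plane, wall, third in convention.sources(seg):
            k = THIRDS.index(third)
            centre = (2 * k + 1) / 6.0
            u = centre + (rng.uniform(-0.5, 0.5) / 3.0) * model.placement_jitter
            draws.append(float(walls[(plane, wall)](u))
                         + rng.normal(0.0, model.measurement_noise_sd_mm))
        out[seg] = float(np.mean(draws))
    return out


def _measure_contour_averaged(truth16, model: ObserverModel, seed,
                              spec_template: PhantomSpec,
                              convention: Convention) -> dict:
    spec = PhantomSpec(
        epi_semi_axes=spec_template.epi_semi_axes,
        thickness_profile=profile_from_truth16(truth16, convention),
        apex_window_mm=spec_template.apex_window_mm,
        contour_noise_sd_mm=model.contour_noise_sd_mm,
        noise_corr_mm=spec_template.noise_corr_mm,
        n_vertices=spec_template.n_vertices,
    )
    study = generate_phantom(spec, seed=seed)
    result = run_pipeline(study, PipelineConfig(convention=convention))
    return dict(result.seg_values)


def simulate_readers(truth_cohort: Sequence[SubjectTruth],
                     model_a: ObserverModel, model_b: ObserverModel,
                     seed: int | None = None,
                     spec_template: PhantomSpec | None = None,
                     convention: Convention | None = None) -> pd.DataFrame:
    """Simulate two independent readers over a truth cohort.

    Returns a tidy table (subject, group, sex, reader, method, segment,
    value_mm) with one row per subject x reader x segment.  Each reader/subject
    combination uses an independent child stream of ``seed``.
    """
    if len(truth_cohort) == 0:
        raise ValueError("empty cohort")
    convention = convention or default_convention()
    spec_template = spec_template or PhantomSpec()
    streams = np.random.SeedSequence(seed).spawn(2 * len(truth_cohort))
    rows = []
    for i, subj in enumerate(truth_cohort):
        for j, (reader, model) in enumerate((("A", model_a), ("B", model_b))):
            ss = streams[2 * i + j]
            if model.kind == "single_caliper":
                vals = _measure_single_caliper(subj.truth16, model,
                                               np.random.default_rng(ss), convention)
            else:
                vals = _measure_contour_averaged(
                    subj.truth16, model, ss, spec_template, convention)
            for seg in SEGMENTS:
                rows.append((subj.subject_id, subj.group, subj.sex, reader,
                             model.kind, seg, vals[seg]))
    return pd.DataFrame(rows, columns=["subject", "group", "sex", "reader",
                                       "method", "segment", "value_mm"])
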