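"""File formats and the bull's-eye report.

Because the vendor export dialect of wall-distance CSVs is not standardised,
the package defines two documented layouts and auto-detects which one it is
reading:

* **wide** — one row per (subject, plane): ``subject,plane,v1,...,vN``.
* **long** — one row per sample: ``subject,plane,sample_index,value_mm``.

Both tolerate ``;`` or tab delimiters and comma decimal marks (European
exports print ``6,53`` for 6.53).  Readers reject malformed files with the
offending row named; writers round-trip losslessly.

The bull's-eye report renders the 16-segment map as the standard AHA polar
plot (6 basal + 6 mid + 4 apical sectors, anterior at 12 o'clock,
counter-clockwise segment order) as SVG text, with sectors thinner than the
flag threshold (default 5 mm) filled red, plus a JSON twin carrying the same
values and flags.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import IncompleteMapError, InvalidValuesError, MalformedFileError
from .geometry import PLANES, ContourPolyline, DistanceSequence, LAXContourPair
from .segmentation import SEGMENTS, ApexDetection, SegmentalMap16

#: Sectors thinner than this are flagged red in the bull's-eye (mm).
FLAG_THRESHOLD_MM_DEFAULT = 5.0


# ---------------------------------------------------------------------------
# Distance CSV


@dataclass(frozen=True)
class DistanceCSVDialect:
    """Layout + lexical conventions of a wall-distance CSV file."""

    layout: str = "wide"          # "wide" | "long"
    delimiter: str = ","
    decimal: str = "."            # "." | ","
    header: bool = True

    def __post_init__(self) -> None:
        if self.layout not in ("wide", "long"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.decimal not in (".", ","):
            raise ValueError(f"decimal mark must be '.' or ',', got {self.decimal!r}")
        if self.decimal == "," and self.delimiter == ",":
            raise ValueError("comma decimals require a non-comma delimiter")


def _sniff_dialect(lines: list) -> DistanceCSVDialect:
    sample = lines[0]
    delim = max([";", "\t", ","], key=sample.count)
    fields = lines[0].split(delim)

    def numericish(tok: str) -> bool:
        try:
            float(tok.strip().replace(",", "."))
            return True
        except ValueError:
            return False

    header = len(fields) > 2 and not numericish(fields[2])
    first_data = lines[1] if (header and len(lines) > 1) else lines[0]
    data_fields = first_data.split(delim)
    decimal = "," if (delim != "," and any("," in f for f in data_fields[2:])) else "."
    n_fields = len(data_fields)
    layout = "long" if n_fields <= 4 else "wide"
    return DistanceCSVDialect(layout=layout, delimiter=delim, decimal=decimal,
                              header=header)


def _parse_value(tok: str, dialect: DistanceCSVDialect, path, row, col) -> float:
    tok = tok.strip()
    if dialect.decimal == ",":
        tok = tok.replace(",", ".")
    try:
        v = float(tok)
    except ValueError:
        raise InvalidValuesError(
            f"{path}: non-numeric value {tok!r} at row {row}, column {col}")
    if not math.isfinite(v) or v < 0:
        raise InvalidValuesError(
            f"{path}: invalid thickness {v!r} at row {row}, column {col}"
            " (must be finite and >= 0)")
    return v


def read_distance_csv(path, dialect: DistanceCSVDialect | None = None) -> dict:
    """Read wall-distance sequences from CSV.

    Returns ``{(subject, plane): DistanceSequence}``.  Layout, delimiter,
    decimal mark and header are auto-detected when ``dialect`` is omitted.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MalformedFileError(f"{path}: empty file")
    dialect = dialect or _sniff_dialect(lines)
    rows = list(csv.reader(lines, delimiter=dialect.delimiter))
    header_row = None
    if dialect.header:
        header_row, rows = rows[0], rows[1:]

    out: dict = {}
    if dialect.layout == "wide":
        expected = len(header_row) if header_row else max(len(r) for r in rows)
        for i, r in enumerate(rows, 1 + dialect.header):
            if len(r) != expected:
                raise MalformedFileError(
                    f"{path}: wide row {i} has {len(r) - 2} values, "
                    f"expected {expected - 2}")
        for i, r in enumerate(rows, 1 + dialect.header):
            if len(r) < 14:  # subject + plane + >= 12 samples
                raise MalformedFileError(
                    f"{path}: wide row {i} has only {len(r) - 2} values")
            subject, plane = r[0].strip(), r[1].strip()
            values = [_parse_value(tok, dialect, path, i, j + 3)
                      for j, tok in enumerate(r[2:])]
            out[(subject, plane)] = DistanceSequence(
                plane_id=plane, values=np.array(values),
                metadata={"subject_id": subject, "source": str(path)})
    else:
        acc: dict = {}
        for i, r in enumerate(rows, 1 + dialect.header):
            if len(r) != 4:
                raise MalformedFileError(
                    f"{path}: long row {i} has {len(r)} fields, expected 4")
            subject, plane = r[0].strip(), r[1].strip()
            try:
                idx = int(r[2])
            except ValueError:
                raise MalformedFileError(
                    f"{path}: non-integer sample index {r[2]!r} at row {i}")
            acc.setdefault((subject, plane), {})[idx] = _parse_value(
                r[3], dialect, path, i, 4)
        for key, samples in acc.items():
            n = len(samples)
            if sorted(samples) != list(range(n)):
                raise MalformedFileError(
                    f"{path}: sample indices for {key} do not form 0..{n - 1}")
            out[key] = DistanceSequence(
                plane_id=key[1], values=np.array([samples[i] for i in range(n)]),
                metadata={"subject_id": key[0], "source": str(path)})
    return out


def write_distance_csv(seqs: Mapping[tuple, DistanceSequence], path,
                       dialect: DistanceCSVDialect | None = None) -> None:
    """Write sequences deterministically ordered by (subject, plane, index)."""
    dialect = dialect or DistanceCSVDialect()
    path = Path(path)

    def fmt(v: float) -> str:
        s = format(float(v), ".12g")  # round-trips to well below 1e-9 mm
        return s.replace(".", ",") if dialect.decimal == "," else s

    lines = []
    keys = sorted(seqs)
    if dialect.layout == "wide":
        if dialect.header:
            n = max(seqs[k].n_samples for k in keys)
            lines.append(dialect.delimiter.join(
                ["subject", "plane"] + [f"v{i + 1}" for i in range(n)]))
        for key in keys:
            seq = seqs[key]
            lines.append(dialect.delimiter.join(
                [key[0], key[1]] + [fmt(v) for v in seq.values]))
    else:
        if dialect.header:
            lines.append(dialect.delimiter.join(
                ["subject", "plane", "sample_index", "value_mm"]))
        for key in keys:
            seq = seqs[key]
            for i, v in enumerate(seq.values):
                lines.append(dialect.delimiter.join([key[0], key[1], str(i), fmt(v)]))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Contour files


def _pair_from_record(rec: Mapping, origin: str) -> LAXContourPair:
    for key in ("plane", "endo", "epi"):
        if key not in rec:
            raise MalformedFileError(f"{origin}: contour record missing {key!r}")
    return LAXContourPair(
        plane_id=str(rec["plane"]),
        endo=ContourPolyline(np.asarray(rec["endo"], dtype=float)),
        epi=ContourPolyline(np.asarray(rec["epi"], dtype=float)),
        apex_marked=bool(rec.get("apex_marked", False)),
        subject_id=str(rec.get("subject", "")),
        reader_id=str(rec.get("reader", "")),
        phase=str(rec.get("phase", "")),
    )


def read_contours_json(path) -> dict:
    """Read one study's contours: a JSON object or list of objects with
    ``{plane, subject, reader, endo: [[x,y]...], epi: [[x,y]...]}`` in mm.
    Returns ``{plane: LAXContourPair}``."""
    path = Path(path)
    data = json.loads(path.read_text())
    records = data if isinstance(data, list) else [data]
    study = {}
    for rec in records:
        pair = _pair_from_record(rec, str(path))
        study[pair.plane_id] = pair
    return study


def write_contours_json(study: Mapping[str, LAXContourPair], path) -> None:
    records = []
    for plane in sorted(study):
        pair = study[plane]
        records.append({
            "plane": pair.plane_id,
            "subject": pair.subject_id,
            "reader": pair.reader_id,
            "apex_marked": pair.apex_marked,
            "endo": np.round(pair.endo.points, 6).tolist(),
            "epi": np.round(pair.epi.points, 6).tolist(),
        })
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_contours_csv(path) -> dict:
    """Read a 4-column contour CSV: plane, role (endo|epi), x, y (mm)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    acc: dict = {}
    start = 1 if lines and lines[0].lower().startswith("plane") else 0
    for i, ln in enumerate(lines[start:], start + 1):
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 4:
            raise MalformedFileError(f"{path}: row {i} has {len(parts)} fields, expected 4")
        plane, role = parts[0], parts[1].lower()
        if role not in ("endo", "epi"):
            raise MalformedFileError(f"{path}: row {i} has unknown role {role!r}")
        try:
            xy = (float(parts[2]), float(parts[3]))
        except ValueError:
            raise MalformedFileError(f"{path}: non-numeric coordinate at row {i}")
        acc.setdefault(plane, {}).setdefault(role, []).append(xy)
    study = {}
    for plane, roles in acc.items():
        if set(roles) != {"endo", "epi"}:
            raise MalformedFileError(f"{path}: plane {plane} missing endo or epi points")
        study[plane] = LAXContourPair(
            plane_id=plane,
            endo=ContourPolyline(np.asarray(roles["endo"])),
            epi=ContourPolyline(np.asarray(roles["epi"])),
        )
    return study


# ---------------------------------------------------------------------------
# Segmental map serialization


def map16_to_dict(map16: SegmentalMap16) -> dict:
    """JSON-ready dict: segment values (mm), aggregates, provenance and the
    per-plane apex audit."""
    return {
        "segments_mm": {s: round(float(map16.seg_values[s]), 4) for s in SEGMENTS},
        "segment_sample_counts": {s: int(map16.seg_counts.get(s, 0)) for s in SEGMENTS},
        "aggregates_mm": {
            "S_AVG_BAS": round(float(map16.s_avg_bas), 4),
            "S_AVG_MID": round(float(map16.s_avg_mid), 4),
            "S_AVG_API": round(float(map16.s_avg_api), 4),
        },
        "provenance": {s: [list(t) for t in map16.provenance.get(s, [])]
                       for s in SEGMENTS},
        "apex_audit": {
            plane: {"run_start": det.run_start, "run_end": det.run_end,
                    "apex_index": det.apex_index, "run_length": det.run_length,
                    "epsilon_mm": det.epsilon_mm}
            for plane, det in map16.apex_audits.items()},
    }


def map16_from_dict(data: Mapping) -> SegmentalMap16:
    seg_values = {s: float(v) for s, v in data["segments_mm"].items()}
    agg = data.get("aggregates_mm", {})
    audits = {
        plane: ApexDetection(run_start=d["run_start"], run_end=d["run_end"],
                             apex_index=d["apex_index"], epsilon_mm=d["epsilon_mm"])
        for plane, d in data.get("apex_audit", {}).items()}
    return SegmentalMap16(
        seg_values=seg_values,
        seg_counts={s: int(v) for s, v in data.get("segment_sample_counts", {}).items()},
        s_avg_bas=float(agg.get("S_AVG_BAS", float(np.mean([seg_values[f"S{i}"] for i in range(1, 7)])))),
        s_avg_mid=float(agg.get("S_AVG_MID", float(np.mean([seg_values[f"S{i}"] for i in range(7, 13)])))),
        s_avg_api=float(agg.get("S_AVG_API", float(np.mean([seg_values[f"S{i}"] for i in range(13, 17)])))),
        provenance={s: [tuple(t) for t in v] for s, v in data.get("provenance", {}).items()},
        apex_audits=audits,
    )


# ---------------------------------------------------------------------------
# Bull's-eye


@dataclass(frozen=True)
class BullseyeReport:
    """16 sector values laid out basal (6) / mid (6) / apical (4), with the
    set of sectors flagged as thinner than ``flag_threshold_mm``."""

    values_mm: Mapping[str, float]
    flag_threshold_mm: float = FLAG_THRESHOLD_MM_DEFAULT
    flagged: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = [s for s in SEGMENTS if s not in self.values_mm]
        if missing:
            raise IncompleteMapError(f"bullseye missing segments: {missing}")
        want = frozenset(s for s in SEGMENTS
                         if self.values_mm[s] < self.flag_threshold_mm)
        object.__setattr__(self, "flagged", want)

    def to_dict(self) -> dict:
        return {
            "flag_threshold_mm": self.flag_threshold_mm,
            "segments": {s: {"value_mm": round(float(self.values_mm[s]), 2),
                             "flagged": s in self.flagged}
                         for s in SEGMENTS},
        }


# ring: (inner radius, outer radius, [segments CCW from anterior at top])
_RINGS = (
    (68.0, 95.0, ["S1", "S2", "S3", "S4", "S5", "S6"]),
    (41.0, 68.0, ["S7", "S8", "S9", "S10", "S11", "S12"]),
    (14.0, 41.0, ["S13", "S14", "S15", "S16"]),
)


def _pt(cx: float, cy: float, r: float, angle_deg: float) -> tuple:
    a = math.radians(angle_deg)
    return (cx + r * math.cos(a), cy - r * math.sin(a))


def _sector_path(cx, cy, r_in, r_out, a_lo, a_hi) -> str:
    p1 = _pt(cx, cy, r_out, a_lo)
    p2 = _pt(cx, cy, r_out, a_hi)
    p3 = _pt(cx, cy, r_in, a_hi)
    p4 = _pt(cx, cy, r_in, a_lo)
    large = 1 if (a_hi - a_lo) > 180 else 0
    return (f"M {p1[0]:.2f} {p1[1]:.2f} "
            f"A {r_out:.2f} {r_out:.2f} 0 {large} 0 {p2[0]:.2f} {p2[1]:.2f} "
            f"L {p3[0]:.2f} {p3[1]:.2f} "
            f"A {r_in:.2f} {r_in:.2f} 0 {large} 1 {p4[0]:.2f} {p4[1]:.2f} Z")


def render_bullseye(map16: SegmentalMap16,
                    flag_threshold_mm: float = FLAG_THRESHOLD_MM_DEFAULT) -> tuple:
    """Render the AHA polar plot.

    Returns ``(svg_text, BullseyeReport)``.  Anterior segments (S1/S7/S13)
    are centred at 12 o'clock; segment order runs counter-clockwise; sectors
    strictly below the threshold are filled red; values are printed to two
    decimals.  The central disc (the excluded apical cap) stays unlabelled.
    """
    report = BullseyeReport(values_mm=dict(map16.seg_values),
                            flag_threshold_mm=flag_threshold_mm)
    cx = cy = 100.0
    parts = [
        '<svg xmlns="http://www.w3.org/2000/svg" width="200" height="200" '
        'viewBox="0 0 200 200">',
        '<g stroke="#333" stroke-width="1">',
    ]
    for r_in, r_out, segs in _RINGS:
        span = 360.0 / len(segs)
        for i, seg in enumerate(segs):
            centre = 90.0 + i * span  # CCW from anterior at top
            a_lo, a_hi = centre - span / 2.0, centre + span / 2.0
            fill = "#d62728" if seg in report.flagged else "#f5f5f0"
            parts.append(f'<path d="{_sector_path(cx, cy, r_in, r_out, a_lo, a_hi)}" '
                         f'fill="{fill}" data-segment="{seg}"/>')
    parts.append(f'<circle cx="{cx}" cy="{cy}" r="{_RINGS[2][0]}" fill="#e0e0e0"/>')
    parts.append("</g>")
    for r_in, r_out, segs in _RINGS:
        span = 360.0 / len(segs)
        r_mid = (r_in + r_out) / 2.0
        for i, seg in enumerate(segs):
            x, y = _pt(cx, cy, r_mid, 90.0 + i * span)
            colour = "#fff" if seg in report.flagged else "#000"
            parts.append(
                f'<text x="{x:.1f}" y="{y + 3:.1f}" font-size="9" '
                f'text-anchor="middle" fill="{colour}" font-family="sans-serif">'
                f'{report.values_mm[seg]:.2f}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n", report
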