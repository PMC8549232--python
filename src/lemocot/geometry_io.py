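"""Data model and file I/O for pressure-mat recordings.

A recording is an ordered sequence of force frames sampled from a grid of
square force sensors (the study mat has 0.80 x 0.80 cm cells sampled at
60 Hz).  All spatial quantities downstream are expressed in millimetres in
*target-layout coordinates*: the origin sits at the centre of the proximal
target, +y points toward the distal target, and +x to the subject's right.
Which mat corner is sensor (0, 0) and which mat axis carries y is a property
of how the mat was laid out for the session; it is externalised in the
``origin_cell`` / ``y_axis`` fields of :class:`MatGeometry` and recorded in
every file header.

Two open text dialects are supported:

``frame_text``
    One header line ``rows=.. cols=.. pitch_mm=.. rate_hz=.. origin_cell=r,c
    y_axis=..``, optional ``layout= ...`` and ``meta= ...`` lines, then per
    frame a ``t=<seconds>`` line followed by ``n_rows`` whitespace-separated
    rows of forces.

``long_csv``
    Columns ``t,row,col,force`` listing only non-zero cells, with a sidecar
    YAML file carrying the geometry, layout and metadata.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("lemocot")

__all__ = [
    "MatGeometry",
    "TargetLayout",
    "PressureFrame",
    "Recording",
    "RecordingFormatError",
    "RecordingValidationError",
    "cell_to_point",
    "point_to_cell",
    "load_recording",
    "save_recording",
    "default_mat_geometry",
]

#: Relative jitter tolerated in inter-frame spacing before a recording is
#: rejected (time-of-touch needs frame ordering, not exact spacing).
FRAME_JITTER_TOLERANCE = 0.10

_Y_AXIS_CHOICES = ("+row", "-row", "+col", "-col")


class RecordingFormatError(ValueError):
    """A recording file does not parse under the declared dialect."""


class RecordingValidationError(ValueError):
    """Parsed data violates a recording invariant."""


@dataclass(frozen=True)
class MatGeometry:
    """Sensor grid geometry plus its registration to layout coordinates.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (>= 1).
    cell_pitch_mm
        Centre-to-centre sensor spacing; the cells are square.  The study
        mat uses 8.0 mm.
    sampling_rate_hz
        Frame rate of the mat (study mat: 60 Hz).
    origin_cell
        Fractional ``(row, col)`` grid position of the proximal-target
        centre, i.e. of the layout origin.
    y_axis
        Which grid axis (and direction) carries layout +y: one of
        ``"+row"``, ``"-row"``, ``"+col"``, ``"-col"``.
    """

    n_rows: int
    n_cols: int
    cell_pitch_mm: float = 8.0
    sampling_rate_hz: float = 60.0
    origin_cell: tuple[float, float] = (0.0, 0.0)
    y_axis: str = "+row"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise RecordingValidationError("grid dimensions must be >= 1")
        if not self.cell_pitch_mm > 0:
            raise RecordingValidationError("cell_pitch_mm must be > 0")
        if not self.sampling_rate_hz > 0:
            raise RecordingValidationError("sampling_rate_hz must be > 0")
        if self.y_axis not in _Y_AXIS_CHOICES:
            raise RecordingValidationError(
                f"y_axis must be one of {_Y_AXIS_CHOICES}, got {self.y_axis!r}"
            )


@dataclass(frozen=True)
class TargetLayout:
    """Positions of the two targets and the zone geometry, in mm.

    The proximal target centre defines the origin; the distal target sits
    30 cm further along +y by default.  Each target owns a zone band of
    ``zone_half_width_mm`` on either side of its centre along y; contacts
    outside both bands are between-target touches.  The target radius is
    configurable (it is not fixed by the test protocol) and is echoed in
    every output header.
    """

    proximal_center: tuple[float, float] = (0.0, 0.0)
    distal_center: tuple[float, float] = (0.0, 300.0)
    target_radius_mm: float = 25.0
    zone_half_width_mm: float = 100.0

    def __post_init__(self) -> None:
        if tuple(self.proximal_center) == tuple(self.distal_center):
            raise RecordingValidationError("target centers must be distinct")
        if not self.target_radius_mm > 0:
            raise RecordingValidationError("target_radius_mm must be > 0")
        if not self.zone_half_width_mm > 0:
            raise RecordingValidationError("zone_half_width_mm must be > 0")
        # Zone bands are defined on y only; they must not overlap, otherwise
        # zoning would be ambiguous.
        gap = abs(self.distal_center[1] - self.proximal_center[1])
        if gap <= 2.0 * self.zone_half_width_mm:
            raise RecordingValidationError(
                "target zone bands overlap: centers are "
                f"{gap:g} mm apart on y with half-width "
                f"{self.zone_half_width_mm:g} mm"
            )

    def center_of(self, target: str) -> tuple[float, float]:
        if target == "proximal":
            return tuple(self.proximal_center)
        if target == "distal":
            return tuple(self.distal_center)
        raise ValueError(f"unknown target {target!r}")


@dataclass(frozen=True)
class PressureFrame:
    """One time-stamped grid of per-sensor forces (device units, >= 0)."""

    timestamp: float
    forces: np.ndarray

    def __post_init__(self) -> None:
        forces = np.asarray(self.forces, dtype=float)
        object.__setattr__(self, "forces", forces)
        if forces.ndim != 2:
            raise RecordingValidationError("forces must be a 2-D array")
        if np.any(forces < 0):
            raise RecordingValidationError("negative force value in frame")


@dataclass
class Recording:
    """An ordered frame sequence plus geometry, layout and trial metadata.

    ``meta`` carries free-form trial metadata; the keys ``subject``,
    ``group`` (stroke/control) and ``leg`` (paretic/non-paretic/dominant/
    non-dominant) are understood downstream.
    """

    geometry: MatGeometry
    layout: TargetLayout
    frames: list[PressureFrame]
    duration_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.frames) < 1:
            raise RecordingValidationError("a Recording must contain >= 1 frame")
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        ts = np.array([f.timestamp for f in self.frames], dtype=float)
        for i, f in enumerate(self.frames):
            if f.forces.shape != shape:
                raise RecordingValidationError(
                    f"frame {i} has shape {f.forces.shape}, expected {shape}"
                )
        if np.any(np.diff(ts) <= 0):
            bad = int(np.argmax(np.diff(ts) <= 0))
            raise RecordingValidationError(
                f"timestamps not strictly increasing at frame {bad + 1}"
            )
        if len(ts) >= 2:
            dt_nominal = 1.0 / self.geometry.sampling_rate_hz
            dts = np.diff(ts)
            if np.any(np.abs(dts - dt_nominal) > FRAME_JITTER_TOLERANCE * dt_nominal):
                bad = int(np.argmax(np.abs(dts - dt_nominal) > FRAME_JITTER_TOLERANCE * dt_nominal))
                raise RecordingValidationError(
                    f"frame spacing at frame {bad + 1} deviates from "
                    f"1/{self.geometry.sampling_rate_hz:g} s by more than "
                    f"{FRAME_JITTER_TOLERANCE:.0%}"
                )
        if self.duration_s is None:
            self.duration_s = float(ts[-1] - ts[0] + 1.0 / self.geometry.sampling_rate_hz)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def force_stack(self) -> np.ndarray:
        """All frames as one ``(n_frames, n_rows, n_cols)`` array."""
        return np.stack([f.forces for f in self.frames])

    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)


def default_mat_geometry() -> MatGeometry:
    """A mat large enough to hold both targets plus heel clearance.

    82 x 32 cells at 8 mm pitch spans y in [-240, 408] mm and x in
    [-124, 124] mm with the proximal target registered at cell (30, 15.5).
    """
    return MatGeometry(
        n_rows=82, n_cols=32, cell_pitch_mm=8.0, sampling_rate_hz=60.0,
        origin_cell=(30.0, 15.5), y_axis="+row",
    )


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def cell_to_point(
    row, col, geometry: MatGeometry, layout: TargetLayout | None = None
) -> np.ndarray:
    """Map sensor indices to the mm coordinates of the cell *centre*.

    Accepts scalars or arrays; returns ``(..., 2)`` points ``(x, y)`` in
    target-layout coordinates.  ``layout`` is accepted for interface
    symmetry but the registration lives entirely in ``geometry``.
    """
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    if np.any(row < 0) or np.any(row > geometry.n_rows - 1) or np.any(col < 0) or np.any(
        col > geometry.n_cols - 1
    ):
        raise IndexError("cell index out of range for mat geometry")
    p = geometry.cell_pitch_mm
    r0, c0 = geometry.origin_cell
    dr = (row - r0) * p
    dc = (col - c0) * p
    if geometry.y_axis == "+row":
        x, y = dc, dr
    elif geometry.y_axis == "-row":
        x, y = dc, -dr
    elif geometry.y_axis == "+col":
        x, y = dr, dc
    else:  # "-col"
        x, y = dr, -dc
    return np.stack([x, y], axis=-1)


def point_to_cell(
    point, geometry: MatGeometry, layout: TargetLayout | None = None
) -> tuple[int, int]:
    """Inverse of :func:`cell_to_point`: the cell whose square contains ``point``."""
    x, y = float(np.asarray(point)[..., 0]), float(np.asarray(point)[..., 1])
    p = geometry.cell_pitch_mm
    r0, c0 = geometry.origin_cell
    if geometry.y_axis == "+row":
        dr, dc = y, x
    elif geometry.y_axis == "-row":
        dr, dc = -y, x
    elif geometry.y_axis == "+col":
        dr, dc = x, y
    else:
        dr, dc = x, -y
    row = int(round(dr / p + r0))
    col = int(round(dc / p + c0))
    if not (0 <= row < geometry.n_rows and 0 <= col < geometry.n_cols):
        raise IndexError(f"point {(x, y)} maps outside the mat")
    return row, col


# ---------------------------------------------------------------------------
# frame_text dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("rows", "cols", "pitch_mm", "rate_hz", "origin_cell", "y_axis")


def _format_header(rec: Recording) -> list[str]:
    g, lay = rec.geometry, rec.layout
    lines = [
        f"rows={g.n_rows} cols={g.n_cols} pitch_mm={g.cell_pitch_mm!r} "
        f"rate_hz={g.sampling_rate_hz!r} "
        f"origin_cell={g.origin_cell[0]!r},{g.origin_cell[1]!r} y_axis={g.y_axis}"
    ]
    lines.append(
        f"layout= proximal={lay.proximal_center[0]!r},{lay.proximal_center[1]!r} "
        f"distal={lay.distal_center[0]!r},{lay.distal_center[1]!r} "
        f"radius_mm={lay.target_radius_mm!r} "
        f"zone_half_width_mm={lay.zone_half_width_mm!r}"
    )
    if rec.meta:
        pairs = " ".join(f"{k}={v}" for k, v in sorted(rec.meta.items()))
        lines.append(f"meta= {pairs}")
    return lines


def _parse_kv(text: str, line_no: int, path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for tok in text.split():
        if "=" not in tok:
            raise RecordingFormatError(
                f"{path}:{line_no}: expected key=value tokens, got {tok!r}"
            )
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def _geometry_from_header(kv: dict[str, str], line_no: int, path: str) -> MatGeometry:
    missing = [k for k in _HEADER_KEYS if k not in kv]
    if missing:
        raise RecordingFormatError(
            f"{path}:{line_no}: malformed header, missing {', '.join(missing)}"
        )
    try:
        oc = tuple(float(v) for v in kv["origin_cell"].split(","))
        return MatGeometry(
            n_rows=int(kv["rows"]), n_cols=int(kv["cols"]),
            cell_pitch_mm=float(kv["pitch_mm"]), sampling_rate_hz=float(kv["rate_hz"]),
            origin_cell=oc, y_axis=kv["y_axis"],
        )
    except (ValueError, TypeError) as exc:
        raise RecordingFormatError(f"{path}:{line_no}: malformed header: {exc}") from exc


def _layout_from_kv(kv: dict[str, str]) -> TargetLayout:
    def pt(s: str) -> tuple[float, float]:
        a, b = s.split(",")
        return (float(a), float(b))

    return TargetLayout(
        proximal_center=pt(kv.get("proximal", "0,0")),
        distal_center=pt(kv.get("distal", "0,300")),
        target_radius_mm=float(kv.get("radius_mm", 25.0)),
        zone_half_width_mm=float(kv.get("zone_half_width_mm", 100.0)),
    )


def _save_frame_text(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        for line in _format_header(rec):
            fh.write(line + "\n")
        for frame in rec.frames:
            fh.write(f"t={frame.timestamp!r}\n")
            for r in range(rec.geometry.n_rows):
                fh.write(" ".join(repr(float(v)) for v in frame.forces[r]) + "\n")


def _load_frame_text(path: Path) -> Recording:
    frames: list[PressureFrame] = []
    layout = TargetLayout()
    meta: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise RecordingFormatError(f"{path}:1: empty file")
    geometry = _geometry_from_header(_parse_kv(lines[0], 1, str(path)), 1, str(path))
    i = 1
    while i < len(lines) and not lines[i].startswith("t="):
        line = lines[i]
        if line.startswith("layout="):
            layout = _layout_from_kv(_parse_kv(line[len("layout="):], i + 1, str(path)))
        elif line.startswith("meta="):
            meta = dict(_parse_kv(line[len("meta="):], i + 1, str(path)))
        elif line.strip():
            raise RecordingFormatError(f"{path}:{i + 1}: unexpected line before frames")
        i += 1
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith("t="):
            raise RecordingFormatError(f"{path}:{i + 1}: expected 't=<seconds>' line")
        try:
            t = float(line[2:])
        except ValueError as exc:
            raise RecordingFormatError(f"{path}:{i + 1}: bad timestamp {line!r}") from exc
        rows = []
        for r in range(geometry.n_rows):
            i += 1
            if i >= len(lines):
                raise RecordingFormatError(
                    f"{path}:{i}: truncated frame at t={t} (row {r} missing)"
                )
            vals = lines[i].split()
            if len(vals) != geometry.n_cols:
                raise RecordingFormatError(
                    f"{path}:{i + 1}: expected {geometry.n_cols} values, got {len(vals)}"
                )
            rows.append([float(v) for v in vals])
        frames.append(PressureFrame(timestamp=t, forces=np.array(rows)))
        i += 1
    return Recording(geometry=geometry, layout=layout, frames=frames, meta=meta)


# ---------------------------------------------------------------------------
# long_csv dialect (sparse CSV + YAML sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _save_long_csv(rec: Recording, path: Path) -> None:
    g, lay = rec.geometry, rec.layout
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "row", "col", "force"])
        for frame in rec.frames:
            rr, cc = np.nonzero(frame.forces)
            # every frame keeps at least its timestamp: an all-zero frame is
            # encoded as a single explicit zero cell so timing round-trips
            if len(rr) == 0:
                w.writerow([repr(frame.timestamp), 0, 0, repr(0.0)])
                continue
            for r, c in zip(rr.tolist(), cc.tolist()):
                w.writerow([repr(frame.timestamp), r, c, repr(float(frame.forces[r, c]))])
    sidecar = {
        "rows": g.n_rows, "cols": g.n_cols, "pitch_mm": g.cell_pitch_mm,
        "rate_hz": g.sampling_rate_hz,
        "origin_cell": [g.origin_cell[0], g.origin_cell[1]], "y_axis": g.y_axis,
        "layout": {
            "proximal": list(lay.proximal_center), "distal": list(lay.distal_center),
            "radius_mm": lay.target_radius_mm,
            "zone_half_width_mm": lay.zone_half_width_mm,
        },
        "meta": dict(rec.meta),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def _load_long_csv(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise RecordingFormatError(f"{path}: sidecar config {sidecar} not found")
    with open(sidecar) as fh:
        cfg = yaml.safe_load(fh)
    try:
        geometry = MatGeometry(
            n_rows=int(cfg["rows"]), n_cols=int(cfg["cols"]),
            cell_pitch_mm=float(cfg["pitch_mm"]), sampling_rate_hz=float(cfg["rate_hz"]),
            origin_cell=tuple(float(v) for v in cfg["origin_cell"]),
            y_axis=str(cfg["y_axis"]),
        )
        lay_cfg = cfg.get("layout", {})
        layout = TargetLayout(
            proximal_center=tuple(lay_cfg.get("proximal", (0.0, 0.0))),
            distal_center=tuple(lay_cfg.get("distal", (0.0, 300.0))),
            target_radius_mm=float(lay_cfg.get("radius_mm", 25.0)),
            zone_half_width_mm=float(lay_cfg.get("zone_half_width_mm", 100.0)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise RecordingFormatError(f"{sidecar}: malformed sidecar config: {exc}") from exc
    meta = dict(cfg.get("meta") or {})

    frames: list[PressureFrame] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["t", "row", "col", "force"]:
            raise RecordingFormatError(
                f"{path}:1: malformed header, expected 't,row,col,force'"
            )
        cur_t: float | None = None
        cur = None
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t, r, c, f = float(row[0]), int(row[1]), int(row[2]), float(row[3])
            except (ValueError, IndexError) as exc:
                raise RecordingFormatError(f"{path}:{line_no}: bad row {row!r}") from exc
            if cur_t is None or t != cur_t:
                if cur is not None:
                    frames.append(PressureFrame(timestamp=cur_t, forces=cur))
                cur_t = t
                cur = np.zeros((geometry.n_rows, geometry.n_cols))
            if not (0 <= r < geometry.n_rows and 0 <= c < geometry.n_cols):
                raise RecordingFormatError(f"{path}:{line_no}: cell ({r},{c}) out of range")
            cur[r, c] = f
        if cur is not None:
            frames.append(PressureFrame(timestamp=cur_t, forces=cur))
    return Recording(geometry=geometry, layout=layout, frames=frames, meta=meta)


# ---------------------------------------------------------------------------
# Public load/save
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path, format: str = "frame_text") -> None:
    """Write ``rec`` to ``path``; ``long_csv`` also writes a ``.yaml`` sidecar.

    Forces round-trip exactly (values are written with full precision) and
    timestamps to well under 1e-6 s.
    """
    rec.validate()
    path = Path(path)
    if format == "frame_text":
        _save_frame_text(rec, path)
    elif format == "long_csv":
        _save_long_csv(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r}")


def load_recording(path, format: str = "frame_text") -> Recording:
    """Read a recording written in the named dialect and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "frame_text":
        return _load_frame_text(path)
    if format == "long_csv":
        return _load_long_csv(path)
    raise ValueError(f"unknown recording format {format!r}")
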