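"""Touch classification and motor-performance error parameters.

The traditional LEMOCOT score is the number of in-target touches in a 20 s
trial.  On a pressure mat the same trial additionally yields, for every
touch, the contact surface, the big-toe endpoint, the centre of pressure
(COP) and, from those, accuracy and consistency measures:

* absolute error  — Euclidean distance of a touch (endpoint or COP) from
  the target centre, ``sqrt((x_i - x_t)^2 + (y_i - y_t)^2)``;
* variable error  — Euclidean distance of a touch from the mean touch
  position of the same leg and target, ``sqrt((x_i - x̄)^2 + (y_i - ȳ)^2)``;
* endpoint–COP distance — how far the controlled point (the big toe) sits
  from the overall force centroid of the foot contact.

Touches are zoned on the y axis only: a band of ``zone_half_width_mm``
around each target centre is that target's zone and everything else is the
between-target zone.  Zone bands and the in/out target disc are closed
(boundary counts toward the target), so boundary behaviour is deterministic
and favours the participant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry_io import TargetLayout

__all__ = [
    "TouchMetrics",
    "TrialSummary",
    "classify_zone",
    "classify_hit",
    "absolute_error",
    "variable_error",
    "endpoint_cop_distance",
    "compute_touch_metrics",
    "summarize_trial",
    "touch_table",
    "surface_density_grid",
]


def classify_zone(point, layout: TargetLayout) -> str:
    """Zone of a point: ``proximal`` / ``distal`` / ``between``, judged on y only.

    Zone bands are closed intervals of half-width ``zone_half_width_mm``
    around each target centre's y; x is ignored (a wild medio-lateral touch
    stays in its y zone and is classified out-of-target by the disc test).
    """
    y = float(np.asarray(point)[..., 1])
    if abs(y - layout.proximal_center[1]) <= layout.zone_half_width_mm:
        return "proximal"
    if abs(y - layout.distal_center[1]) <= layout.zone_half_width_mm:
        return "distal"
    return "between"


def classify_hit(point, target_center, radius_mm: float) -> str:
    """``in`` iff the point lies within the closed target disc, else ``out``."""
    return "in" if absolute_error(point, target_center) <= radius_mm else "out"


def absolute_error(point, target_center) -> float:
    """Euclidean distance from a touch location to the target centre (mm)."""
    p = np.asarray(point, dtype=float)
    t = np.asarray(target_center, dtype=float)
    return float(np.hypot(p[..., 0] - t[..., 0], p[..., 1] - t[..., 1]))


def variable_error(points) -> np.ndarray:
    """Per-point distance from the group mean position (mm).

    ``points`` is an ``(n, 2)`` array of touch locations for one leg and one
    target.  With fewer than two points the measure is undefined and an
    array of NaN markers is returned (one participant producing a single
    touch per target is a real occurrence, not an error).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return np.full(len(pts), np.nan)
    mean = pts.mean(axis=0)
    return np.hypot(pts[:, 0] - mean[0], pts[:, 1] - mean[1])


def endpoint_cop_distance(endpoint, cop) -> float:
    """Euclidean distance between the endpoint and the COP of one touch (mm)."""
    e = np.asarray(endpoint, dtype=float)
    c = np.asarray(cop, dtype=float)
    return float(np.hypot(e[0] - c[0], e[1] - c[1]))


@dataclass
class TouchMetrics:
    """One touch event joined with its per-touch error parameters.

    ``var_err_*`` are NaN for between-target touches, for touches outside
    the configured parameter scope, and whenever the touch's leg+target
    group holds fewer than two scoped touches.
    """

    event: object  # TouchEvent; kept loose to avoid a circular import
    abs_err_endpoint_mm: float
    abs_err_cop_mm: float
    endpoint_cop_distance_mm: float
    var_err_endpoint_mm: float = float("nan")
    var_err_cop_mm: float = float("nan")


@dataclass
class TrialSummary:
    """Per-trial counts and parameter means for one leg of one subject."""

    counts: dict[str, int]
    per_target_counts: dict[str, dict[str, int]]
    traditional_score: int
    mean_surface_cm2: float
    mean_endpoint_cop_distance_mm: float
    mean_abs_err_endpoint_mm: float
    mean_abs_err_cop_mm: float
    mean_var_err_endpoint_mm: float
    mean_var_err_cop_mm: float
    n_events: int
    meta: dict = field(default_factory=dict)
    target_radius_mm: float = float("nan")
    params_scope: str = "in_out"

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d

    def to_json(self, path) -> None:
        def clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        with open(path, "w") as fh:
            json.dump({k: clean(v) for k, v in self.to_dict().items()}, fh,
                      indent=2, default=str)


def _scoped(metrics_events, scope: str) -> bool:
    hit = metrics_events.hit
    return hit == "in" if scope == "in_only" else hit in ("in", "out")


def compute_touch_metrics(
    events: Sequence,
    layout: TargetLayout,
    params_scope: str = "in_out",
    variable_error_pooling: str = "per_target",
) -> list[TouchMetrics]:
    """Join each TouchEvent with its error parameters.

    Absolute errors are measured against the centre of the touch's zone
    target; between-target touches carry NaN errors (they have no target).
    Variable error groups touches by target within the trial's single leg
    (``variable_error_pooling="pooled"`` instead centres each touch on its
    target and pools both targets into one scatter group).
    ``params_scope`` selects which touches enter the variable-error groups
    and the trial means: in+out (default) or in only.
    """
    if params_scope not in ("in_out", "in_only"):
        raise ValueError(f"unknown params_scope {params_scope!r}")
    out: list[TouchMetrics] = []
    for ev in events:
        if ev.zone == "between":
            out.append(TouchMetrics(ev, float("nan"), float("nan"),
                                    endpoint_cop_distance(ev.endpoint, ev.cop)))
            continue
        center = layout.center_of(ev.zone)
        out.append(
            TouchMetrics(
                ev,
                abs_err_endpoint_mm=absolute_error(ev.endpoint, center),
                abs_err_cop_mm=absolute_error(ev.cop, center),
                endpoint_cop_distance_mm=endpoint_cop_distance(ev.endpoint, ev.cop),
            )
        )

    # variable error: within leg and target, over the scoped touches
    if variable_error_pooling == "per_target":
        groups = {"proximal": [], "distal": []}
        for m in out:
            if m.event.zone != "between" and _scoped(m.event, params_scope):
                groups[m.event.zone].append(m)
        group_lists = list(groups.values())
    elif variable_error_pooling == "pooled":
        pooled = [m for m in out
                  if m.event.zone != "between" and _scoped(m.event, params_scope)]
        group_lists = [pooled]
    else:
        raise ValueError(f"unknown variable_error_pooling {variable_error_pooling!r}")

    for members in group_lists:
        if not members:
            continue
        if variable_error_pooling == "pooled":
            centers = np.array([layout.center_of(m.event.zone) for m in members])
            eps = np.array([m.event.endpoint for m in members]) - centers
            cops = np.array([m.event.cop for m in members]) - centers
        else:
            eps = np.array([m.event.endpoint for m in members])
            cops = np.array([m.event.cop for m in members])
        ve_ep = variable_error(eps)
        ve_cop = variable_error(cops)
        for m, ve, vc in zip(members, ve_ep, ve_cop):
            m.var_err_endpoint_mm = float(ve)
            m.var_err_cop_mm = float(vc)
    return out


def _nanmean(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def summarize_trial(
    metrics: Sequence[TouchMetrics],
    meta: dict | None = None,
    layout: TargetLayout | None = None,
    params_scope: str = "in_out",
) -> TrialSummary:
    """Counts, traditional score and parameter means for one trial.

    ``in + out + between`` always equals the number of touch events; the
    traditional score is the in-target count.  Parameter means are computed
    over the scoped (default in+out) touches only; between-target touches
    never contribute to parameter means.  Undefined variable errors (groups
    of fewer than two touches) are excluded from the means.
    """
    counts = {"in": 0, "out": 0, "between": 0}
    per_target = {
        "proximal": {"in": 0, "out": 0},
        "distal": {"in": 0, "out": 0},
    }
    for m in metrics:
        ev = m.event
        counts[ev.hit] += 1
        if ev.zone != "between":
            per_target[ev.zone][ev.hit] += 1
    scoped = [m for m in metrics if m.event.zone != "between" and _scoped(m.event, params_scope)]
    return TrialSummary(
        counts=counts,
        per_target_counts=per_target,
        traditional_score=counts["in"],
        mean_surface_cm2=_nanmean(m.event.surface_cm2 for m in scoped),
        mean_endpoint_cop_distance_mm=_nanmean(m.endpoint_cop_distance_mm for m in scoped),
        mean_abs_err_endpoint_mm=_nanmean(m.abs_err_endpoint_mm for m in scoped),
        mean_abs_err_cop_mm=_nanmean(m.abs_err_cop_mm for m in scoped),
        mean_var_err_endpoint_mm=_nanmean(m.var_err_endpoint_mm for m in scoped),
        mean_var_err_cop_mm=_nanmean(m.var_err_cop_mm for m in scoped),
        n_events=len(metrics),
        meta=dict(meta or {}),
        target_radius_mm=(layout.target_radius_mm if layout is not None else float("nan")),
        params_scope=params_scope,
    )


TOUCH_TABLE_COLUMNS = [
    "subject", "group", "leg", "touch_index", "t_touch_s", "zone", "hit",
    "intended_target", "endpoint_x_mm", "endpoint_y_mm", "cop_x_mm", "cop_y_mm",
    "surface_cm2", "abs_err_ep_mm", "abs_err_cop_mm", "ep_cop_dist_mm",
    "var_err_ep_mm", "var_err_cop_mm",
]


def touch_table(metrics: Sequence[TouchMetrics], meta: dict | None = None) -> pd.DataFrame:
    """One row per touch, in the exported CSV/JSON schema."""
    meta = dict(meta or {})
    rows = []
    for i, m in enumerate(metrics):
        ev = m.event
        rows.append({
            "subject": meta.get("subject", ""),
            "group": meta.get("group", ""),
            "leg": meta.get("leg", ""),
            "touch_index": i,
            "t_touch_s": ev.t_touch_s,
            "zone": ev.zone,
            "hit": ev.hit,
            "intended_target": ev.intended_target,
            "endpoint_x_mm": ev.endpoint[0],
            "endpoint_y_mm": ev.endpoint[1],
            "cop_x_mm": ev.cop[0],
            "cop_y_mm": ev.cop[1],
            "surface_cm2": ev.surface_cm2,
            "abs_err_ep_mm": m.abs_err_endpoint_mm,
            "abs_err_cop_mm": m.abs_err_cop_mm,
            "ep_cop_dist_mm": m.endpoint_cop_distance_mm,
            "var_err_ep_mm": m.var_err_endpoint_mm,
            "var_err_cop_mm": m.var_err_cop_mm,
        })
    return pd.DataFrame(rows, columns=TOUCH_TABLE_COLUMNS)


def surface_density_grid(recording, events) -> np.ndarray:
    """Per-cell counts of touch contacts: how many touches pressed each cell.

    The grid mirrors the density-plot view of the contact surface
    distribution; each touch contributes 1 to every cell active at its time
    of touch.
    """
    grid = np.zeros((recording.geometry.n_rows, recording.geometry.n_cols), dtype=int)
    for ev in events:
        mask = ev.episode.region_mask(ev.touch_frame)
        grid += mask.astype(int)
    return grid
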