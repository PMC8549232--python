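"""Synthetic pressure-mat recordings with full ground truth.

The simulator emulates a 20 s alternating toe-touch trial: a schedule of
proximal/distal reaches at a configurable rate, each rendered as a
truncated isotropic 2-D Gaussian force blob sampled at the sensor-cell
centres.  Every phenomenon the analysis measures has a dial:

* endpoint accuracy/consistency — per-touch endpoint = target centre +
  ``endpoint_bias_mm`` + isotropic Gaussian scatter of sd
  ``endpoint_scatter_sd_mm``;
* endpoint–COP separation — a second "forefoot pad" blob of equal mass is
  placed laterally outward from the target (so it can never sit closer to
  the target than the toe and never captures the endpoint), putting the
  combined force centroid a configurable offset away from the toe; with
  ``heel_contact`` a large heel blob toward the subject plus a connecting
  arch ridge emulates a whole-foot landing;
* contact surface — blob peak force and spatial sd;
* between-target touches — with probability ``p_between`` per reach, a
  short drag contact is inserted in the between-target zone;
* sensor noise — i.i.d. per-cell noise clipped below the activation
  threshold, so it perturbs forces without creating phantom contacts.

Each touch renders one approach-ramp frame (half force, displaced 16 mm
radially away from the target) followed by full-contact frames, so the
time-of-touch rule is exercised nontrivially.  The emitted
:class:`SimulationTruth` records, per scheduled touch, the true endpoint,
the true COP (force centroid of the noiseless rendered contact), the true
cell count, and zone/hit labels obtained by applying the configured layout
to the true endpoints.

``simulate_cohort`` additionally generates whole study cohorts: either
fully rendered recordings pushed through the detection pipeline, or — the
fast default for statistical work — observation tables drawn directly from
the condition-implied parameter distributions (log-normal with a
subject-level random intercept, the generative form of the downstream
mixed models).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry_io import (
    MatGeometry,
    PressureFrame,
    Recording,
    TargetLayout,
    cell_to_point,
    default_mat_geometry,
)
from .scoring import classify_hit, classify_zone

__all__ = [
    "SimulationConfig",
    "TruthTouch",
    "SimulationTruth",
    "simulate_recording",
    "emulate_manual_count",
    "LegCondition",
    "CohortProfile",
    "default_cohort_profile",
    "null_cohort_profile",
    "simulate_cohort",
]

#: Radial displacement of the approach-ramp frame away from the target (mm).
APPROACH_OFFSET_MM = 16.0


@dataclass(frozen=True)
class SimulationConfig:
    """Dials of one simulated trial.

    Defaults describe a mid-range healthy performance: 1.5 touches/s for
    20 s, 10 mm endpoint scatter (≈96% of touches inside a 25 mm target
    disc), an 8 mm toe–COP offset, a toe-sized contact blob and faint
    sub-threshold sensor noise.
    """

    trial_duration_s: float = 20.0
    touch_rate_hz: float = 1.5
    endpoint_bias_mm: tuple[float, float] = (0.0, 0.0)
    endpoint_scatter_sd_mm: float = 10.0
    cop_offset_mean_mm: float = 8.0
    cop_offset_sd_mm: float = 2.0
    blob_peak_force: float = 50.0
    blob_sd_mm: float = 6.0
    p_between: float = 0.0
    heel_contact: bool = False
    heel_offset_mm: float = 100.0
    noise_sd: float = 0.3
    seed: int = 0
    #: resample endpoint scatter that lands within this margin of the
    #: in/out disc boundary or of a zone-band edge; 0 disables the guard.
    boundary_guard_mm: float = 0.0
    dwell_frames: int = 9
    activation_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_between <= 1.0:
            raise ValueError("p_between must be a probability")
        if min(self.endpoint_scatter_sd_mm, self.cop_offset_sd_mm,
               self.noise_sd, self.boundary_guard_mm) < 0:
            raise ValueError("standard deviations and guards must be >= 0")
        if self.touch_rate_hz <= 0 or self.trial_duration_s <= 0:
            raise ValueError("touch rate and duration must be positive")
        if self.dwell_frames < 2:
            raise ValueError("dwell_frames must be >= 2 (ramp + contact)")


@dataclass
class TruthTouch:
    """Ground truth for one scheduled contact."""

    index: int
    kind: str  # "target" | "between"
    intended_target: str
    onset_frame: int
    touch_frame: int
    endpoint: tuple[float, float]
    cop: tuple[float, float]
    n_cells: int
    surface_cm2: float
    zone: str
    hit: str


@dataclass
class SimulationTruth:
    """Ground-truth schedule and per-trial counts of a simulated recording."""

    touches: list[TruthTouch]
    counts: dict[str, int]
    seed: int

    @property
    def in_count(self) -> int:
        return self.counts["in"]

    @property
    def n_touches(self) -> int:
        return len(self.touches)


# ---------------------------------------------------------------------------
# blob rendering
# ---------------------------------------------------------------------------

def _cell_centers(geometry: MatGeometry) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(geometry.n_rows), np.arange(geometry.n_cols),
                         indexing="ij")
    return cell_to_point(rr, cc, geometry)  # (rows, cols, 2)


def _gaussian_blob(centers: np.ndarray, center, peak: float, sd: float) -> np.ndarray:
    d2 = (centers[..., 0] - center[0]) ** 2 + (centers[..., 1] - center[1]) ** 2
    return peak * np.exp(-d2 / (2.0 * sd * sd))


def _arch_ridge(centers: np.ndarray, a, b, peak: float, sd: float) -> np.ndarray:
    """A Gaussian ridge along segment a→b (the foot arch connecting toe and heel)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    denom = float(ab @ ab)
    rel = centers - a
    t = (rel[..., 0] * ab[0] + rel[..., 1] * ab[1]) / denom
    proj = a + t[..., None] * ab
    d2 = ((centers - proj) ** 2).sum(axis=-1)
    ridge = peak * np.exp(-d2 / (2.0 * sd * sd))
    # generous overlap with the toe and heel blobs so the rendered foot is a
    # single connected component at any sensor-grid alignment
    ridge[(t < 0.08) | (t > 0.92)] = 0.0
    return ridge


def _blob_extent_ok(center, peak: float, sd: float, thr: float,
                    geometry: MatGeometry) -> bool:
    if peak <= thr:
        return True
    r_star = sd * np.sqrt(2.0 * np.log(peak / thr))
    corners = _corner_points(geometry)
    xs, ys = corners[:, 0], corners[:, 1]
    return (
        center[0] - r_star >= xs.min() and center[0] + r_star <= xs.max()
        and center[1] - r_star >= ys.min() and center[1] + r_star <= ys.max()
    )


def _corner_points(geometry: MatGeometry) -> np.ndarray:
    rows = [0, geometry.n_rows - 1]
    cols = [0, geometry.n_cols - 1]
    return np.array([cell_to_point(r, c, geometry) for r in rows for c in cols])


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def _draw_endpoint(rng, target_center, cfg: SimulationConfig,
                   layout: TargetLayout, geometry: MatGeometry,
                   touch_index: int) -> np.ndarray:
    """Endpoint = target + bias + scatter, resampled against guard/mat limits."""
    t = np.asarray(target_center, float)
    bias = np.asarray(cfg.endpoint_bias_mm, float)
    corners = _corner_points(geometry)
    # keep the whole rendered contact on the mat: toe blob + approach ramp on
    # all sides, the lateral pad blob in x, and the heel toward the subject (-y)
    margin = 3.5 * cfg.blob_sd_mm + APPROACH_OFFSET_MM + 8.0
    x_extra = 2.0 * (cfg.cop_offset_mean_mm + 4.0 * cfg.cop_offset_sd_mm)
    low_extra = 0.0
    if cfg.heel_contact:
        low_extra = cfg.heel_offset_mm + 3.5 * cfg.blob_sd_mm
    for _ in range(1000):
        e = t + bias + rng.normal(0.0, cfg.endpoint_scatter_sd_mm, size=2)
        if not (corners[:, 0].min() + margin + x_extra <= e[0]
                <= corners[:, 0].max() - margin - x_extra
                and corners[:, 1].min() + margin + low_extra <= e[1]
                <= corners[:, 1].max() - margin):
            continue
        if cfg.boundary_guard_mm > 0:
            g = cfg.boundary_guard_mm
            r = float(np.hypot(e[0] - t[0], e[1] - t[1]))
            if abs(r - layout.target_radius_mm) < g:
                continue  # too close to the in/out disc boundary
            if abs(e[1] - t[1]) > layout.zone_half_width_mm - g:
                continue  # too close to a zone-band edge
        return e
    raise ValueError(
        f"touch {touch_index}: cannot place the contact blob on the mat "
        "(endpoint distribution leaves no room for the rendered contact)"
    )


def simulate_recording(
    cfg: SimulationConfig,
    layout: TargetLayout | None = None,
    geometry: MatGeometry | None = None,
    meta: dict | None = None,
) -> tuple[Recording, SimulationTruth]:
    """Render one alternating-touch trial and its ground truth.

    Reproducible: the same configuration (including its seed) always
    produces a bit-identical recording and truth.
    """
    layout = layout or TargetLayout()
    geometry = geometry or default_mat_geometry()
    rng = np.random.default_rng(cfg.seed)
    rate = geometry.sampling_rate_hz
    n_frames = int(round(cfg.trial_duration_s * rate))
    frames_per_cycle = max(int(round(rate / cfg.touch_rate_hz)), cfg.dwell_frames + 2)
    if cfg.p_between > 0 and frames_per_cycle < cfg.dwell_frames + 5:
        raise ValueError(
            "touch_rate_hz too high to fit between-target drags: "
            f"{frames_per_cycle} frames per cycle < dwell + 5"
        )

    centers = _cell_centers(geometry)
    thr = cfg.activation_threshold
    stack = np.zeros((n_frames, geometry.n_rows, geometry.n_cols))
    touches: list[TruthTouch] = []

    def contact_blobs(endpoint, target_center, cfg: SimulationConfig, rng) -> list:
        blobs = [(tuple(endpoint), cfg.blob_peak_force, cfg.blob_sd_mm)]
        d = rng.normal(cfg.cop_offset_mean_mm, cfg.cop_offset_sd_mm)
        d = max(d, 0.0)
        if d > 1e-9:
            # equal-mass pad at twice the offset, laterally away from the
            # target, puts the combined centroid ~d from the toe without
            # ever producing cells closer to the target than the toe
            s = 1.0 if endpoint[0] >= target_center[0] else -1.0
            pad = (float(endpoint[0]) + s * 2.0 * d, float(endpoint[1]))
            blobs.append((pad, cfg.blob_peak_force, cfg.blob_sd_mm))
        if cfg.heel_contact:
            heel = (float(endpoint[0]), float(endpoint[1]) - cfg.heel_offset_mm)
            blobs.append((heel, 0.6 * cfg.blob_peak_force, 2.0 * cfg.blob_sd_mm))
            blobs.append(("arch", endpoint, heel))
        return blobs

    def render_touch(onset, endpoint, target_center, cfg, touch_index):
        e = np.asarray(endpoint, float)
        t = np.asarray(target_center, float)
        radial = e - t
        norm = float(np.hypot(*radial))
        u = radial / norm if norm > 1e-9 else np.array([0.0, 1.0])
        ramp_pos = e + APPROACH_OFFSET_MM * u

        raw = contact_blobs(e, t, cfg, rng)
        blobs = []
        arch = None
        for b in raw:
            if b[0] == "arch":
                arch = b
            else:
                blobs.append(b)

        def field_at(pos_shift, scale):
            f = np.zeros_like(stack[0])
            for center, peak, sd in blobs:
                c = (center[0] + pos_shift[0], center[1] + pos_shift[1])
                if not _blob_extent_ok(c, peak * scale, sd, thr, geometry):
                    raise ValueError(
                        f"touch {touch_index}: contact blob at "
                        f"{tuple(np.round(c, 1))} extends beyond the mat"
                    )
                f += _gaussian_blob(centers, c, peak * scale, sd)
            if arch is not None:
                _, toe, heel = arch
                a = (toe[0] + pos_shift[0], toe[1] + pos_shift[1])
                bpt = (heel[0] + pos_shift[0], heel[1] + pos_shift[1])
                f += _arch_ridge(centers, a, bpt, 0.5 * cfg.blob_peak_force * scale,
                                 0.8 * cfg.blob_sd_mm)
            f[f < thr] = 0.0
            return f

        shift_ramp = ramp_pos - e
        f_ramp = field_at(shift_ramp, 0.5)
        f_full = field_at((0.0, 0.0), 1.0)
        last = min(onset + cfg.dwell_frames - 1, n_frames - 1)
        stack[onset] = np.maximum(stack[onset], f_ramp)
        for k in range(onset + 1, last + 1):
            stack[k] = np.maximum(stack[k], f_full)
        return f_full, onset + 1

    def truth_from_field(f_full) -> tuple[tuple[float, float], int, float]:
        mask = f_full >= thr
        w = f_full[mask]
        pts = centers[mask]
        cop = (pts * w[:, None]).sum(axis=0) / w.sum()
        n_cells = int(mask.sum())
        surface = n_cells * (geometry.cell_pitch_mm / 10.0) ** 2
        return (float(cop[0]), float(cop[1])), n_cells, surface

    index = 0
    k = 0
    onset = 1
    while onset + cfg.dwell_frames - 1 < n_frames - 1:
        target = "proximal" if k % 2 == 0 else "distal"
        t_center = np.asarray(layout.center_of(target), float)
        endpoint = _draw_endpoint(rng, t_center, cfg, layout, geometry, index)
        f_full, touch_frame = render_touch(onset, endpoint, t_center, cfg, index)
        cop, n_cells, surface = truth_from_field(f_full)
        zone = classify_zone(endpoint, layout)
        if zone == "between":
            hit = "between"
        else:
            hit = classify_hit(endpoint, layout.center_of(zone), layout.target_radius_mm)
        touches.append(TruthTouch(
            index=index, kind="target", intended_target=target,
            onset_frame=onset, touch_frame=touch_frame,
            endpoint=(float(endpoint[0]), float(endpoint[1])),
            cop=cop, n_cells=n_cells, surface_cm2=surface, zone=zone, hit=hit,
        ))
        index += 1

        if cfg.p_between > 0 and rng.random() < cfg.p_between:
            drag_onset = onset + cfg.dwell_frames + 1
            if drag_onset + 2 <= min(onset + frames_per_cycle - 2, n_frames - 2):
                y_mid = 0.5 * (layout.proximal_center[1] + layout.distal_center[1])
                half_band = 0.5 * abs(layout.distal_center[1] - layout.proximal_center[1]) \
                    - layout.zone_half_width_mm
                g = max(cfg.boundary_guard_mm, 8.0)
                dy = rng.normal(0.0, 15.0)
                dy = float(np.clip(dy, -(half_band - g), half_band - g))
                drag_center = np.array([rng.normal(0.0, 8.0), y_mid + dy])
                blobs = [(tuple(drag_center), 0.7 * cfg.blob_peak_force,
                          0.8 * cfg.blob_sd_mm)]
                f_drag = np.zeros_like(stack[0])
                for center, peak, sd in blobs:
                    if not _blob_extent_ok(center, peak, sd, thr, geometry):
                        raise ValueError(
                            f"touch {index}: drag blob at "
                            f"{tuple(np.round(center, 1))} extends beyond the mat"
                        )
                    f_drag += _gaussian_blob(centers, center, peak, sd)
                f_drag[f_drag < thr] = 0.0
                for kk in range(drag_onset, drag_onset + 3):
                    stack[kk] = np.maximum(stack[kk], f_drag)
                cop, n_cells, surface = truth_from_field(f_drag)
                next_target = "proximal" if (k + 1) % 2 == 0 else "distal"
                touches.append(TruthTouch(
                    index=index, kind="between", intended_target=next_target,
                    onset_frame=drag_onset, touch_frame=drag_onset,
                    endpoint=(float(drag_center[0]), float(drag_center[1])),
                    cop=cop, n_cells=n_cells, surface_cm2=surface,
                    zone="between", hit="between",
                ))
                index += 1

        k += 1
        onset += frames_per_cycle

    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd, size=stack.shape)
        np.clip(noise, 0.0, 0.95 * thr, out=noise)
        stack += noise

    ts = np.arange(n_frames) / rate
    frames = [PressureFrame(timestamp=float(t), forces=stack[i])
              for i, t in enumerate(ts)]
    rec = Recording(geometry=geometry, layout=layout, frames=frames,
                    duration_s=cfg.trial_duration_s, meta=dict(meta or {}))
    counts = {"in": 0, "out": 0, "between": 0}
    for touch in touches:
        counts[touch.hit] += 1
    truth = SimulationTruth(touches=touches, counts=counts, seed=cfg.seed)
    return rec, truth


def emulate_manual_count(
    truth: SimulationTruth, miscount_rate_per_touch: float, seed: int
) -> int:
    """A human examiner's count: the true in-count plus binomial overcounts.

    Each touch (of any kind) carries ``miscount_rate_per_touch`` probability
    of being mistakenly counted, emulating an examiner whose error grows
    with how much is happening on the mat.
    """
    if not 0.0 <= miscount_rate_per_touch <= 1.0:
        raise ValueError("miscount rate must be a probability")
    rng = np.random.default_rng(seed)
    over = int(rng.binomial(truth.n_touches, miscount_rate_per_touch))
    return truth.in_count + over


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LegCondition:
    """Group-level performance profile of one group × leg cell."""

    touch_rate_hz: float = 1.5
    touch_rate_sd: float = 0.15
    endpoint_scatter_sd_mm: float = 10.0
    cop_offset_mean_mm: float = 8.0
    cop_offset_sd_mm: float = 2.0
    blob_sd_mm: float = 6.0
    heel_contact: bool = False
    p_between: float = 0.02

    def to_sim_config(self, rng, seed: int, **overrides) -> SimulationConfig:
        rate = max(self.touch_rate_hz + rng.normal(0.0, self.touch_rate_sd), 0.3)
        kw = dict(
            touch_rate_hz=rate,
            endpoint_scatter_sd_mm=self.endpoint_scatter_sd_mm,
            cop_offset_mean_mm=self.cop_offset_mean_mm,
            cop_offset_sd_mm=self.cop_offset_sd_mm,
            blob_sd_mm=self.blob_sd_mm,
            heel_contact=self.heel_contact,
            p_between=self.p_between,
            seed=seed,
        )
        kw.update(overrides)
        return SimulationConfig(**kw)


@dataclass(frozen=True)
class CohortProfile:
    """Per-cell conditions plus the analytic observation-table noise model.

    The analytic path draws each log-parameter as
    ``Ln(param) = ln(condition-implied mean) + slope·(in_count − count_ref)
    + u_subject + ε`` with ``u ~ N(0, subject_sd_log²)`` and
    ``ε ~ N(0, resid_sd_log²)`` — exactly the generative form assumed by the
    downstream mixed models.
    """

    stroke_paretic: LegCondition = LegCondition(
        touch_rate_hz=0.80, touch_rate_sd=0.20, endpoint_scatter_sd_mm=13.0,
        cop_offset_mean_mm=12.0, cop_offset_sd_mm=3.0, blob_sd_mm=7.0,
        heel_contact=True, p_between=0.25,
    )
    stroke_non_paretic: LegCondition = LegCondition(
        touch_rate_hz=1.00, touch_rate_sd=0.20, endpoint_scatter_sd_mm=11.5,
        cop_offset_mean_mm=10.0, cop_offset_sd_mm=2.5, blob_sd_mm=6.5,
        heel_contact=False, p_between=0.15,
    )
    control_dominant: LegCondition = LegCondition(
        touch_rate_hz=1.80, touch_rate_sd=0.25, endpoint_scatter_sd_mm=10.0,
        cop_offset_mean_mm=7.0, cop_offset_sd_mm=2.0, blob_sd_mm=5.5,
        heel_contact=False, p_between=0.015,
    )
    control_non_dominant: LegCondition = LegCondition(
        touch_rate_hz=1.70, touch_rate_sd=0.25, endpoint_scatter_sd_mm=10.0,
        cop_offset_mean_mm=7.0, cop_offset_sd_mm=2.0, blob_sd_mm=5.5,
        heel_contact=False, p_between=0.015,
    )
    subject_sd_log: float = 0.20
    resid_sd_log: float = 0.20
    count_slope_log: float = 0.0
    count_ref: float = 25.0
    miscount_rate: float = 0.05
    trial_duration_s: float = 20.0

    def cell(self, group: str, leg: str) -> LegCondition:
        key = f"{group}_{leg}".replace("-", "_")
        return getattr(self, key)


def default_cohort_profile() -> CohortProfile:
    """Study-like conditions: slower, less accurate, flatter-footed stroke legs."""
    return CohortProfile()


def null_cohort_profile() -> CohortProfile:
    """All four group × leg cells identical (for calibration work)."""
    c = LegCondition()
    return CohortProfile(
        stroke_paretic=c, stroke_non_paretic=c,
        control_dominant=c, control_non_dominant=c,
    )


_PARAM_COLUMNS = ("surface_cm2", "ep_cop_dist_mm", "abs_err_ep_mm",
                  "abs_err_cop_mm", "var_err_ep_mm", "var_err_cop_mm")


def _implied_means(cond: LegCondition, thr: float = 1.0, peak: float = 50.0) -> dict:
    """Condition-implied parameter means (closed-form approximations).

    Surface uses the truncation radius of the toe blob (doubled cells for a
    heel landing); scatter-driven errors use the Rayleigh mean σ√(π/2) of
    isotropic 2-D scatter; COP errors add the offset dispersion in
    quadrature.
    """
    r_star = cond.blob_sd_mm * np.sqrt(2.0 * np.log(peak / thr))
    area_factor = 3.5 if cond.heel_contact else 2.0  # toe + pad (+ heel/arch)
    surface = area_factor * np.pi * r_star**2 / 100.0
    ray = np.sqrt(np.pi / 2.0)
    scatter = cond.endpoint_scatter_sd_mm
    cop_sd = np.sqrt(scatter**2 + cond.cop_offset_sd_mm**2)
    return {
        "surface_cm2": surface,
        "ep_cop_dist_mm": max(cond.cop_offset_mean_mm, 1.0),
        "abs_err_ep_mm": ray * scatter,
        "abs_err_cop_mm": ray * cop_sd + 0.5 * cond.cop_offset_mean_mm,
        "var_err_ep_mm": ray * scatter,
        "var_err_cop_mm": ray * cop_sd,
    }


_CELLS = (
    ("stroke", "paretic"), ("stroke", "non-paretic"),
    ("control", "dominant"), ("control", "non-dominant"),
)


def simulate_cohort(
    n_stroke: int,
    n_control: int,
    profile: CohortProfile | None = None,
    seed: int = 0,
    render: bool = False,
    layout: TargetLayout | None = None,
    geometry: MatGeometry | None = None,
    detection_config=None,
) -> pd.DataFrame:
    """Generate a stats-ready observation table (one row per subject-leg).

    With ``render=True`` every subject-leg trial is rendered to a pressure
    recording and pushed through the full detection/scoring pipeline; the
    default analytic path draws the table directly from the
    condition-implied distributions (much faster, exactly the mixed-model
    generative form).  Ground-truth conditions are recorded in
    ``df.attrs["profile"]`` and the seed in ``df.attrs["seed"]``.
    """
    if n_stroke < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    profile = profile or default_cohort_profile()
    rng = np.random.default_rng(seed)
    rows = []
    if render:
        from .scoring import compute_touch_metrics, summarize_trial
        from .touch_detection import DetectionConfig, extract_touch_events

        layout = layout or TargetLayout()
        geometry = geometry or default_mat_geometry()
        det = detection_config or DetectionConfig()
    subj_idx = 0
    for group, n in (("stroke", n_stroke), ("control", n_control)):
        legs = ("paretic", "non-paretic") if group == "stroke" else ("dominant", "non-dominant")
        for _ in range(n):
            subject = f"{group[0]}{subj_idx:03d}"
            subj_idx += 1
            u = {p: rng.normal(0.0, profile.subject_sd_log) for p in _PARAM_COLUMNS}
            u_rate = rng.normal(0.0, 1.0)
            for leg in legs:
                cond = profile.cell(group, leg)
                if render:
                    sim_seed = int(rng.integers(0, 2**31 - 1))
                    cfg = cond.to_sim_config(
                        rng, sim_seed, trial_duration_s=profile.trial_duration_s,
                        boundary_guard_mm=0.0,
                    )
                    rec, truth = simulate_recording(cfg, layout, geometry,
                                                    meta={"subject": subject,
                                                          "group": group, "leg": leg})
                    events = extract_touch_events(rec, det)
                    metrics = compute_touch_metrics(events, layout)
                    summ = summarize_trial(metrics, rec.meta, layout)
                    manual = emulate_manual_count(truth, profile.miscount_rate,
                                                  int(rng.integers(0, 2**31 - 1)))
                    rows.append({
                        "subject": subject, "group": group, "leg": leg,
                        "in_count": summ.counts["in"],
                        "out_count": summ.counts["out"],
                        "between_count": summ.counts["between"],
                        "manual_count": manual,
                        "surface_cm2": summ.mean_surface_cm2,
                        "ep_cop_dist_mm": summ.mean_endpoint_cop_distance_mm,
                        "abs_err_ep_mm": summ.mean_abs_err_endpoint_mm,
                        "abs_err_cop_mm": summ.mean_abs_err_cop_mm,
                        "var_err_ep_mm": summ.mean_var_err_endpoint_mm,
                        "var_err_cop_mm": summ.mean_var_err_cop_mm,
                        "true_in_count": truth.counts["in"],
                    })
                    continue

                # analytic path
                rate = max(cond.touch_rate_hz + cond.touch_rate_sd * (0.7 * u_rate
                           + 0.7 * rng.normal()), 0.2)
                n_target = max(int(round(rate * profile.trial_duration_s)), 1)
                sd = max(cond.endpoint_scatter_sd_mm, 1e-9)
                radius = (layout or TargetLayout()).target_radius_mm
                p_in = 1.0 - np.exp(-(radius**2) / (2.0 * sd**2))
                n_in = int(rng.binomial(n_target, p_in))
                n_out = n_target - n_in
                n_between = int(rng.binomial(n_target, cond.p_between))
                manual = n_in + int(rng.binomial(n_target + n_between,
                                                 profile.miscount_rate))
                implied = _implied_means(cond)
                row = {
                    "subject": subject, "group": group, "leg": leg,
                    "in_count": n_in, "out_count": n_out,
                    "between_count": n_between, "manual_count": manual,
                    "true_in_count": n_in,
                }
                for p in _PARAM_COLUMNS:
                    ln = (np.log(implied[p])
                          + profile.count_slope_log * (n_in - profile.count_ref)
                          + u[p] + rng.normal(0.0, profile.resid_sd_log))
                    row[p] = float(np.exp(ln))
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["seed"] = seed
    df.attrs["profile"] = dataclasses.asdict(profile)
    df.attrs["rendered"] = bool(render)
    return df
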