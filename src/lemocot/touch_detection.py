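"""Contact-episode segmentation and per-touch localisation.

The raw recording is a force movie; the analysis needs discrete touches.
A frame is *active* when the total force of its above-threshold cells
reaches an episode gate; a contact episode is a maximal run of at least
``min_duration`` consecutive active frames, separated from its neighbours
by at least one inactive frame.  Within every frame the analysed region is
the largest connected component of above-threshold cells (the foot); stray
noisy cells and any secondary disjoint contact are discarded and logged —
the test protocol puts a single foot on the mat.

Per episode the module computes:

* the **endpoint** — the big-toe location, extracted from the force
  distribution as the force-weighted centroid of the active cells within
  ``toe_radius_mm`` of the extremal cell (the active cell nearest the
  intended target).  A whole-foot landing therefore resolves to the toe
  end of the contact rather than to the middle of the foot;
* the **time of touch** — the earliest frame at which the endpoint is
  closest to the intended target's centre (ties break to the earlier
  frame);
* the **COP** — the force-weighted mean position of the whole contact
  region at the time of touch;
* the **contact surface** — active-cell count times the cell area, in cm².

Which target a touch was aimed at follows the test's alternation protocol:
a touch ending inside a target zone is assigned that target; a touch that
never reaches a zone (a between-target drag) is assigned the alternation
prediction — the opposite of the previous in/out touch's target, proximal
for the first touch of a trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry_io import MatGeometry, PressureFrame, Recording, cell_to_point
from .scoring import classify_hit, classify_zone

logger = logging.getLogger("lemocot")

__all__ = [
    "DetectionConfig",
    "ContactEpisode",
    "TouchEvent",
    "detect_episodes",
    "cop_location",
    "endpoint_location",
    "time_of_touch",
    "contact_surface",
    "infer_intended_target",
    "extract_touch_events",
]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class DetectionConfig:
    """Tuning constants of the touch-detection algorithm.

    force_threshold
        Per-cell activation threshold, raw device units.
    min_total_force
        Episode gate: a frame participates in an episode only when the sum
        of its above-threshold forces reaches this value.
    min_duration
        Minimum episode length in frames; 2 rejects single-frame noise.
    toe_radius_mm
        Radius of the endpoint neighbourhood around the extremal cell
        (default 20 mm, roughly the width of a big toe, 2–3 cells).
    connectivity
        Cell adjacency for connected components, 4 or 8.
    """

    force_threshold: float = 1.0
    min_total_force: float = 3.0
    min_duration: int = 2
    toe_radius_mm: float = 20.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.force_threshold <= 0 or self.min_total_force <= 0:
            raise ValueError("force thresholds must be positive")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.toe_radius_mm <= 0:
            raise ValueError("toe_radius_mm must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ContactEpisode:
    """A maximal run of consecutive active frames with per-frame regions.

    ``masks[i]`` is the boolean active-region mask of global frame
    ``start_frame + i`` (the largest connected component of that frame).
    """

    start_frame: int
    end_frame: int  # inclusive
    masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("episode start after end")
        if len(self.masks) != self.end_frame - self.start_frame + 1:
            raise ValueError("one region mask required per frame in span")
        for i, m in enumerate(self.masks):
            if not m.any():
                raise ValueError(f"frame {self.start_frame + i} of episode has no active cell")

    @property
    def frame_indices(self) -> range:
        return range(self.start_frame, self.end_frame + 1)

    def region_mask(self, frame_index: int) -> np.ndarray:
        if not self.start_frame <= frame_index <= self.end_frame:
            raise IndexError("frame index outside episode span")
        return self.masks[frame_index - self.start_frame]


@dataclass
class TouchEvent:
    """One detected touch with its localisation at the time of touch."""

    episode: ContactEpisode
    intended_target: str  # "proximal" | "distal"
    touch_frame: int
    t_touch_s: float
    endpoint: tuple[float, float]
    cop: tuple[float, float]
    surface_cm2: float
    zone: str  # "proximal" | "distal" | "between"
    hit: str  # "in" | "out" | "between"

    def __post_init__(self) -> None:
        if not self.episode.start_frame <= self.touch_frame <= self.episode.end_frame:
            raise ValueError("touch_frame outside episode span")
        if (self.hit == "between") != (self.zone == "between"):
            raise ValueError("hit is 'between' exactly when zone is 'between'")


def _largest_component(mask: np.ndarray, forces: np.ndarray, connectivity: int) -> np.ndarray:
    """Largest connected component; ties by total force, then by lowest row."""
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return np.zeros_like(mask)
    if n == 1:
        return labels == 1
    sizes = ndimage.sum_labels(np.ones_like(forces), labels, index=range(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        totals = ndimage.sum_labels(forces, labels, index=best)
        best = best[totals == totals.max()]
        if len(best) > 1:
            min_rows = [np.nonzero(labels == b)[0].min() for b in best]
            best = best[[int(np.argmin(min_rows))]]
    return labels == int(best[0])


def detect_episodes(rec: Recording, cfg: DetectionConfig | None = None) -> list[ContactEpisode]:
    """Segment the recording into ordered, disjoint contact episodes."""
    cfg = cfg or DetectionConfig()
    stack = rec.force_stack()
    above = np.where(stack >= cfg.force_threshold, stack, 0.0)
    frame_force = above.sum(axis=(1, 2))
    gated = frame_force >= cfg.min_total_force

    episodes: list[ContactEpisode] = []
    n = len(gated)
    i = 0
    while i < n:
        if not gated[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and gated[j + 1]:
            j += 1
        if j - i + 1 >= cfg.min_duration:
            masks = []
            multi_contact = False
            for k in range(i, j + 1):
                mask_k = stack[k] >= cfg.force_threshold
                region = _largest_component(mask_k, stack[k], cfg.connectivity)
                if mask_k.sum() > region.sum():
                    multi_contact = True
                masks.append(region)
            if multi_contact:
                logger.debug(
                    "episode frames %d-%d: secondary disjoint contact ignored "
                    "(largest component kept)", i, j,
                )
            episodes.append(ContactEpisode(start_frame=i, end_frame=j, masks=masks))
        i = j + 1
    return episodes


def _region_points_forces(
    frame: PressureFrame, region: np.ndarray, geometry: MatGeometry
) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.nonzero(region)
    pts = cell_to_point(rr, cc, geometry)
    return pts, frame.forces[rr, cc]


def cop_location(frame: PressureFrame, region: np.ndarray, geometry: MatGeometry) -> np.ndarray:
    """Force-weighted mean of the region's cell centres, ``Σ f_i p_i / Σ f_i``."""
    pts, f = _region_points_forces(frame, region, geometry)
    if len(f) == 0 or f.sum() <= 0:
        raise ValueError("COP undefined: region empty or total force is zero")
    return (pts * f[:, None]).sum(axis=0) / f.sum()


def endpoint_location(
    frame: PressureFrame,
    region: np.ndarray,
    intended_target: Sequence[float],
    cfg: DetectionConfig,
    geometry: MatGeometry,
) -> np.ndarray:
    """Big-toe location from the force distribution of the contact region.

    The extremal cell is the active cell whose centre lies nearest the
    intended target's centre; the endpoint is the force-weighted centroid
    of the active cells within ``toe_radius_mm`` of it.  For a contact
    smaller than the toe neighbourhood this reduces to the region's COP.
    """
    pts, f = _region_points_forces(frame, region, geometry)
    if len(f) == 0 or f.sum() <= 0:
        raise ValueError("endpoint undefined: region empty or total force is zero")
    target = np.asarray(intended_target, dtype=float)
    d_target = np.hypot(pts[:, 0] - target[0], pts[:, 1] - target[1])
    extremal = pts[int(np.argmin(d_target))]
    near = np.hypot(pts[:, 0] - extremal[0], pts[:, 1] - extremal[1]) <= cfg.toe_radius_mm
    f_near = f[near]
    return (pts[near] * f_near[:, None]).sum(axis=0) / f_near.sum()


def time_of_touch(
    episode: ContactEpisode,
    rec: Recording,
    intended_target: Sequence[float],
    cfg: DetectionConfig,
) -> int:
    """Earliest frame of the episode whose endpoint is closest to the target."""
    target = np.asarray(intended_target, dtype=float)
    best_frame = episode.start_frame
    best_d = np.inf
    for k in episode.frame_indices:
        ep = endpoint_location(rec.frames[k], episode.region_mask(k), target, cfg, rec.geometry)
        d = float(np.hypot(ep[0] - target[0], ep[1] - target[1]))
        if d < best_d:  # strict: ties keep the earlier frame
            best_d = d
            best_frame = k
    return best_frame


def contact_surface(frame: PressureFrame, region: np.ndarray, geometry: MatGeometry) -> float:
    """Contact area of the region in cm² (cell count × pitch²)."""
    n = int(np.count_nonzero(region))
    if n == 0:
        raise ValueError("contact surface undefined for an empty region")
    return n * (geometry.cell_pitch_mm / 10.0) ** 2


def infer_intended_target(
    episode: ContactEpisode,
    rec: Recording,
    previous_event: TouchEvent | None,
    cfg: DetectionConfig | None = None,
) -> str:
    """Which target the touch was aimed at.

    If the final-frame contact ends inside a target zone, it is that zone's
    target (located via the final frame's region COP — for a toe-sized
    contact the COP and the endpoint coincide).  Otherwise the alternation
    protocol predicts the opposite of the previous in/out touch's target,
    defaulting to proximal at the start of a trial.
    """
    last = episode.end_frame
    cop = cop_location(rec.frames[last], episode.region_mask(last), rec.geometry)
    zone = classify_zone(cop, rec.layout)
    if zone in ("proximal", "distal"):
        return zone
    if previous_event is None or previous_event.hit == "between":
        prev_target = None
    else:
        prev_target = previous_event.intended_target
    if prev_target is None:
        return "proximal"
    return "distal" if prev_target == "proximal" else "proximal"


def extract_touch_events(rec: Recording, cfg: DetectionConfig | None = None) -> list[TouchEvent]:
    """Full per-trial detection: episodes → one TouchEvent per episode.

    Deterministic: the same recording and configuration always produce the
    identical event list.
    """
    cfg = cfg or DetectionConfig()
    events: list[TouchEvent] = []
    last_in_out: TouchEvent | None = None
    ts = rec.timestamps()
    for episode in detect_episodes(rec, cfg):
        intended = infer_intended_target(episode, rec, last_in_out, cfg)
        target_center = np.asarray(rec.layout.center_of(intended), dtype=float)
        tf = time_of_touch(episode, rec, target_center, cfg)
        region = episode.region_mask(tf)
        frame = rec.frames[tf]
        endpoint = endpoint_location(frame, region, target_center, cfg, rec.geometry)
        cop = cop_location(frame, region, rec.geometry)
        surface = contact_surface(frame, region, rec.geometry)
        zone = classify_zone(endpoint, rec.layout)
        if zone == "between":
            hit = "between"
        else:
            hit = classify_hit(endpoint, rec.layout.center_of(zone), rec.layout.target_radius_mm)
        event = TouchEvent(
            episode=episode,
            intended_target=intended,
            touch_frame=tf,
            t_touch_s=float(ts[tf]),
            endpoint=(float(endpoint[0]), float(endpoint[1])),
            cop=(float(cop[0]), float(cop[1])),
            surface_cm2=surface,
            zone=zone,
            hit=hit,
        )
        events.append(event)
        if hit in ("in", "out"):
            last_in_out = event
    return events
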