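import numpy as np
import pytest
from scipy.spatial import Delaunay

from lemocot import (
    DetectionConfig,
    cell_to_point,
    contact_surface,
    cop_location,
    detect_episodes,
    endpoint_location,
    extract_touch_events,
    infer_intended_target,
    simulate_recording,
    SimulationConfig,
    time_of_touch,
)


def blob(cells):
    """Frame spec from an iterable of (row, col, force)."""
    return {(r, c): f for r, c, f in cells}


def square(r0, c0, size=3, force=10.0):
    return blob((r, c, force) for r in range(r0, r0 + size) for c in range(c0, c0 + size))


class TestEpisodeSegmentation:
    def test_all_zero_recording_gives_no_episodes(self, make_recording):
        rec = make_recording([{}] * 10)
        assert detect_episodes(rec) == []

    def test_single_blob_span(self, make_recording):
        specs = [{}] * 3 + [square(10, 5)] * 8 + [{}] * 4
        rec = make_recording(specs)
        eps = detect_episodes(rec)
        assert len(eps) == 1
        assert (eps[0].start_frame, eps[0].end_frame) == (3, 10)

    def test_silent_frame_splits_episodes(self, make_recording):
        specs = [square(10, 5)] * 4 + [{}] + [square(30, 5)] * 4
        eps = detect_episodes(make_recording(specs))
        assert len(eps) == 2
        assert eps[0].end_frame == 3 and eps[1].start_frame == 5

    def test_short_runs_rejected(self, make_recording):
        cfg = DetectionConfig(min_duration=3)
        specs = [square(10, 5)] * 2 + [{}] + [square(10, 5)] * 3
        eps = detect_episodes(make_recording(specs), cfg)
        assert len(eps) == 1 and eps[0].start_frame == 3

    def test_episode_partition_is_disjoint_and_complete(self, make_recording):
        rng = np.random.default_rng(5)
        specs = []
        for _ in range(40):
            if rng.random() < 0.5:
                specs.append(square(int(rng.integers(2, 40)), int(rng.integers(2, 10))))
            else:
                specs.append({})
        rec = make_recording(specs)
        cfg = DetectionConfig()
        eps = detect_episodes(rec, cfg)
        seen = set()
        for ep in eps:
            span = set(ep.frame_indices)
            assert not span & seen
            seen |= span
        stack = rec.force_stack()
        above = np.where(stack >= cfg.force_threshold, stack, 0.0)
        gated = above.sum(axis=(1, 2)) >= cfg.min_total_force
        # every gated frame is covered unless it sits in a run shorter than
        # min_duration
        runs = []
        i = 0
        while i < len(gated):
            if gated[i]:
                j = i
                while j + 1 < len(gated) and gated[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        expected = set()
        for i, j in runs:
            if j - i + 1 >= cfg.min_duration:
                expected |= set(range(i, j + 1))
        assert seen == expected

    def test_largest_component_keeps_foot_not_noise(self, make_recording):
        foot = square(10, 5, size=3)
        stray = {(40, 2): 5.0}
        rec = make_recording([{**foot, **stray}] * 3)
        eps = detect_episodes(rec)
        assert len(eps) == 1
        assert eps[0].masks[0].sum() == 9
        assert not eps[0].masks[0][40, 2]


class TestLocalisation:
    def test_cop_single_cell_is_cell_center(self, make_recording, geometry):
        rec = make_recording([{(10, 7): 5.0}] * 2)
        ep = detect_episodes(rec, DetectionConfig(min_total_force=1.0))[0]
        cop = cop_location(rec.frames[0], ep.region_mask(0), geometry)
        assert np.allclose(cop, cell_to_point(10, 7, geometry))

    def test_cop_is_force_weighted_mean(self, make_recording, geometry):
        # cells one pitch apart in x with forces 1 and 3: weighted x = 6 mm
        rec = make_recording([{(10, 7): 1.0, (10, 8): 3.0}] * 2)
        ep = detect_episodes(rec, DetectionConfig(min_total_force=1.0))[0]
        cop = cop_location(rec.frames[0], ep.region_mask(0), geometry)
        x0 = cell_to_point(10, 7, geometry)[0]
        assert np.allclose(cop, (x0 + 6.0, 0.0))

    def test_cop_of_uniform_symmetric_region_is_centroid(self, make_recording, geometry):
        rec = make_recording([square(9, 6, size=3, force=4.0)] * 2)
        ep = detect_episodes(rec)[0]
        cop = cop_location(rec.frames[0], ep.region_mask(0), geometry)
        assert np.allclose(cop, cell_to_point(10, 7, geometry))

    def test_cop_zero_force_degenerate(self, make_recording, geometry):
        rec = make_recording([{(10, 7): 5.0}] * 2)
        empty = np.zeros((geometry.n_rows, geometry.n_cols), dtype=bool)
        with pytest.raises(ValueError, match="COP undefined"):
            cop_location(rec.frames[0], empty, geometry)

    def test_cop_in_convex_hull_of_region(self, make_recording, geometry):
        from scipy.spatial import QhullError

        rng = np.random.default_rng(11)
        checked_hull = 0
        for _ in range(25):
            # random connected-ish patches: a square plus random extra cells
            cells = dict(square(int(rng.integers(5, 30)), int(rng.integers(2, 10)),
                                size=int(rng.integers(2, 4))))
            for _ in range(4):
                r, c = int(rng.integers(5, 35)), int(rng.integers(2, 14))
                cells[(r, c)] = float(rng.uniform(1, 20))
            rec = make_recording([cells] * 2)
            for ep in detect_episodes(rec):
                mask = ep.region_mask(ep.start_frame)
                rr, cc = np.nonzero(mask)
                pts = cell_to_point(rr, cc, geometry)
                cop = cop_location(rec.frames[ep.start_frame], mask, geometry)
                try:
                    tri = Delaunay(pts)
                    assert tri.find_simplex(cop) >= 0
                    checked_hull += 1
                except QhullError:  # degenerate (collinear) region
                    assert pts[:, 0].min() - 1e-9 <= cop[0] <= pts[:, 0].max() + 1e-9
                    assert pts[:, 1].min() - 1e-9 <= cop[1] <= pts[:, 1].max() + 1e-9
        assert checked_hull >= 10

    def test_endpoint_of_single_cell_region(self, make_recording, geometry):
        rec = make_recording([{(10, 7): 5.0}] * 2)
        ep = detect_episodes(rec, DetectionConfig(min_total_force=1.0))[0]
        e = endpoint_location(rec.frames[0], ep.region_mask(0), (0.0, 0.0),
                              DetectionConfig(), geometry)
        assert np.allclose(e, cell_to_point(10, 7, geometry))

    def test_toe_heel_region_resolves_to_toe(self, make_recording, geometry, layout):
        """A toe blob joined to a heel blob by an arch band localises the toe."""
        toe = [(10, 7, 10.0), (10, 8, 10.0), (11, 7, 10.0)]
        arch = [(r, 7, 2.0) for r in range(2, 10)]  # band toward the subject
        heel = [(r, c, 10.0) for r in range(-5 + 5, 2) for c in range(6, 10)]
        cells = blob(toe + arch + heel)
        rec = make_recording([cells] * 2)
        ep = detect_episodes(rec)[0]
        assert ep.region_mask(0).sum() == len(cells)  # one connected region
        cfg = DetectionConfig()
        target = np.asarray(layout.proximal_center)
        e = endpoint_location(rec.frames[0], ep.region_mask(0), target, cfg, geometry)
        cop = cop_location(rec.frames[0], ep.region_mask(0), geometry)
        toe_centroid = np.mean([cell_to_point(r, c, geometry) for r, c, _ in toe], axis=0)
        assert np.hypot(*(e - toe_centroid)) <= geometry.cell_pitch_mm
        assert not np.allclose(e, cop)
        assert e[1] > cop[1]  # endpoint on the toe (target) side

    def test_surface_area_arithmetic(self, make_recording, geometry):
        rec = make_recording([{(10, 7): 5.0}] * 2)
        ep = detect_episodes(rec, DetectionConfig(min_total_force=1.0))[0]
        assert contact_surface(rec.frames[0], ep.region_mask(0), geometry) == pytest.approx(0.64)
        rec10 = make_recording([blob((10, c, 5.0) for c in range(2, 12))] * 2)
        ep10 = detect_episodes(rec10)[0]
        assert contact_surface(rec10.frames[0], ep10.region_mask(0), geometry) == pytest.approx(6.4)

    def test_surface_shrinks_with_threshold(self, make_recording, geometry):
        cells = {(10, c): float(c) for c in range(2, 12)}
        rec = make_recording([cells] * 2)
        areas = []
        for thr in (1.0, 4.0, 8.0):
            eps = detect_episodes(rec, DetectionConfig(force_threshold=thr))
            areas.append(contact_surface(rec.frames[0], eps[0].region_mask(0), geometry))
        assert areas == sorted(areas, reverse=True)


class TestTimeOfTouch:
    def test_stationary_endpoint_picks_start_frame(self, make_recording):
        rec = make_recording([square(10, 5)] * 6)
        ep = detect_episodes(rec)[0]
        assert time_of_touch(ep, rec, (0.0, 0.0), DetectionConfig()) == ep.start_frame

    def test_approach_then_retreat_picks_minimum(self, make_recording):
        # blob slides toward the target (row 10 = y 0) then away again
        rows = [16, 13, 11, 10, 12, 15]
        rec = make_recording([square(r, 7, size=1, force=10.0) for r in rows])
        ep = detect_episodes(rec, DetectionConfig(min_total_force=1.0))[0]
        assert time_of_touch(ep, rec, (0.0, 0.0), DetectionConfig()) == 3

    def test_tie_breaks_to_earlier_frame(self, make_recording):
        rows = [12, 10, 14, 10, 13]
        rec = make_recording([square(r, 7, size=1, force=10.0) for r in rows])
        ep = detect_episodes(rec, DetectionConfig(min_total_force=1.0))[0]
        assert time_of_touch(ep, rec, (0.0, 0.0), DetectionConfig()) == 1


class TestIntendedTarget:
    def test_episode_ending_near_distal_is_distal(self, make_recording):
        # row 46 -> y = 288 mm, inside the distal zone
        rec = make_recording([square(45, 7)] * 3)
        ep = detect_episodes(rec)[0]
        assert infer_intended_target(ep, rec, None) == "distal"

    def test_between_drag_alternates_after_proximal(self, make_recording):
        rec = make_recording([square(28, 7)] * 3)  # y ~ 148: between zone
        ep = detect_episodes(rec)[0]
        events = extract_touch_events(make_recording([square(10, 7)] * 3))
        prev = events[0]
        assert prev.hit in ("in", "out") and prev.intended_target == "proximal"
        assert infer_intended_target(ep, rec, prev) == "distal"

    def test_first_between_episode_defaults_to_proximal(self, make_recording):
        rec = make_recording([square(28, 7)] * 3)
        ep = detect_episodes(rec)[0]
        assert infer_intended_target(ep, rec, None) == "proximal"


def test_event_extraction_is_deterministic():
    cfg = SimulationConfig(trial_duration_s=6.0, seed=21, noise_sd=0.3, p_between=0.2)
    rec1, _ = simulate_recording(cfg)
    rec2, _ = simulate_recording(cfg)
    assert np.array_equal(rec1.force_stack(), rec2.force_stack())
    ev1 = extract_touch_events(rec1)
    ev2 = extract_touch_events(rec2)
    assert len(ev1) == len(ev2) > 0
    for a, b in zip(ev1, ev2):
        assert (a.touch_frame, a.endpoint, a.cop, a.surface_cm2, a.zone, a.hit) == \
            (b.touch_frame, b.endpoint, b.cop, b.surface_cm2, b.zone, b.hit)
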