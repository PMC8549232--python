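import numpy as np
import pytest

from lemocot import (
    DetectionConfig,
    MatGeometry,
    PressureFrame,
    Recording,
    TargetLayout,
)


@pytest.fixture
def geometry() -> MatGeometry:
    """A small mat registered with the proximal target at cell (10, 7.5)."""
    return MatGeometry(n_rows=56, n_cols=16, cell_pitch_mm=8.0,
                       sampling_rate_hz=60.0, origin_cell=(10.0, 7.5), y_axis="+row")


@pytest.fixture
def layout() -> TargetLayout:
    return TargetLayout()


@pytest.fixture
def detection_config() -> DetectionConfig:
    return DetectionConfig()


def build_recording(geometry, layout, frame_specs, meta=None) -> Recording:
    """Recording from a list of {(row, col): force} dicts, one per frame."""
    frames = []
    for i, spec in enumerate(frame_specs):
        forces = np.zeros((geometry.n_rows, geometry.n_cols))
        for (r, c), f in spec.items():
            forces[r, c] = f
        frames.append(PressureFrame(timestamp=i / geometry.sampling_rate_hz,
                                    forces=forces))
    return Recording(geometry=geometry, layout=layout, frames=frames,
                     meta=dict(meta or {}))


@pytest.fixture
def make_recording(geometry, layout):
    def _make(frame_specs, meta=None):
        return build_recording(geometry, layout, frame_specs, meta)

    return _make
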