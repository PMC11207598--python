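import numpy as np
import pytest

from moiretrack import Pose6DOF, default_marker_spec
from moiretrack.scene import RenderOptions, external_camera, render_marker_view


@pytest.fixture(scope="session")
def spec():
    return default_marker_spec()


@pytest.fixture(scope="session")
def camera():
    return external_camera()


@pytest.fixture(scope="session")
def reference_frame(spec, camera):
    """Noiseless render of the marker at a generic (non-grid-aligned) reference pose."""
    return render_marker_view(REFERENCE_POSE, camera, spec, RenderOptions())


@pytest.fixture(scope="session")
def reference_analysis(reference_frame, spec):
    from moiretrack.detection import analyse_frame

    return analyse_frame(reference_frame, spec)


#: generic benchtop reference placement used across detection tests; a small
#: offset avoids the pathological perfectly-pixel-aligned identity pose
REFERENCE_POSE = Pose6DOF(tx=0.23, ty=-0.31, pitch=-0.013, yaw=0.021, roll=0.4)


@pytest.fixture(scope="session")
def reference_pose():
    return REFERENCE_POSE


def pose_offset(base: Pose6DOF, **delta) -> Pose6DOF:
    d = dict(tx=base.tx, ty=base.ty, tz=base.tz, pitch=base.pitch,
             yaw=base.yaw, roll=base.roll)
    for k, v in delta.items():
        d[k] += v
    return Pose6DOF(**d)
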