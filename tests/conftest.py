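import numpy as np
import pytest

from etmorph import LandmarkId, LandmarkSet, Point3
from etmorph.geometry import RigidTransform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rigid(rng: np.random.Generator) -> RigidTransform:
    """A uniformly random proper rotation (QR of a Gaussian matrix) plus a
    translation within ±100 mm."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return RigidTransform(q, rng.uniform(-100, 100, 3))


@pytest.fixture
def flat_landmarks():
    """A symmetric subject whose four anchor landmarks are coplanar (z=0),
    so all three reference planes coincide; the right ET chord makes 30°
    with that plane and is 20 mm long."""
    return LandmarkSet(
        "flat",
        {
            LandmarkId.IOM_R: Point3(-30, -55, 0),
            LandmarkId.IOM_L: Point3(30, -55, 0),
            LandmarkId.MF_R: Point3(-58, -8, 0),
            LandmarkId.MF_L: Point3(58, -8, 0),
            LandmarkId.EAC_R: Point3(-60, 0, 0),
            LandmarkId.EAC_L: Point3(60, 0, 0),
            LandmarkId.PO_R: Point3(-30, -20, -10),
            LandmarkId.TO_R: Point3(-30 - 17.320508075688775, -20, 0),
            LandmarkId.PO_L: Point3(30, -20, -10),
            LandmarkId.TO_L: Point3(30 + 17.320508075688775, -20, 0),
        },
    )
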