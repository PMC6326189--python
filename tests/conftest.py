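import numpy as np
import pytest

from vertseg.core_io import RoiBox
from vertseg.phantom import PhantomSpec, generate_phantom

# User ROI sized like a typical hand-drawn box: the default 64x44 px body
# plus a little surrounding tissue.
USER_LX, USER_LY = 72, 52


@pytest.fixture(scope="session")
def clean_phantom():
    """Five identical-pitch bodies, no noise, no rotation."""
    spec = PhantomSpec(n_bodies=5, seed=3, noise_sigma=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(n_bodies=4, seed=7, noise_sigma=0.05)
    return generate_phantom(spec)


@pytest.fixture
def user_roi(clean_phantom):
    _, truth = clean_phantom
    mid = len(truth.centers) // 2
    return RoiBox(center=truth.centers[mid], lx=USER_LX, ly=USER_LY)


def center_roi(truth, index, lx=USER_LX, ly=USER_LY):
    return RoiBox(center=truth.centers[index], lx=lx, ly=ly)


def rectangle_edge_map(w=64, h=44, angle=0.0, shape=(100, 120)):
    """Rasterised outline of a w x h rectangle rotated by ``angle`` (CCW)."""
    from vertseg.core_io import _rotation_matrix
    from vertseg.roi_refinement import EdgeMap

    E = np.zeros(shape, dtype=bool)
    cr, cc = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    t = np.linspace(0, 1, 500, endpoint=False)
    segs = []
    corners = [(-h / 2, -w / 2), (-h / 2, w / 2), (h / 2, w / 2), (h / 2, -w / 2)]
    for a, b in zip(corners, corners[1:] + corners[:1]):
        segs.append(np.outer(1 - t, a) + np.outer(t, b))
    pts = np.vstack(segs) @ _rotation_matrix(angle).T
    rr = np.round(pts[:, 0] + cr).astype(int)
    cc2 = np.round(pts[:, 1] + cc).astype(int)
    E[rr, cc2] = True
    return EdgeMap(E)
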