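import numpy as np
import pytest

import musetransfer as mt


@pytest.fixture(scope="session")
def phantom600():
    """One mild-warp phantom at the cheap 600-px test scale, exact landmarks."""
    return mt.generate_phantom(seed=7, shape=(600, 600))


@pytest.fixture(scope="session")
def phantom600_result(phantom600):
    """End-to-end pipeline output on the shared phantom (computed once)."""
    s = phantom600
    return mt.run_pipeline(s.annotated_he, s.clean_he, s.raw_muse, s.control_points)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def scattered_point_set(rng, n, shape=(1000, 1000), margin=0.1):
    """Well-spread random landmark locations (pixel units) for fit tests."""
    lo = np.array([shape[1], shape[0]]) * margin
    hi = np.array([shape[1], shape[0]]) * (1 - margin)
    return rng.uniform(lo, hi, (n, 2))


def pairs_from_transform(t, moving_px, shape=(1000, 1000)):
    """Exact control-point pairs generated by a known moving-to-fixed warp."""
    fixed = mt.denormalize_points(t(mt.normalize_points(moving_px, shape)), shape)
    return mt.ControlPointSet(fixed, moving_px, shape, shape)
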