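import numpy as np
import pytest

import lvthick as lt


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def healthy_truth():
    """A fixed realistic 16-segment truth vector (basal thickest, apex thinnest)."""
    return lt.generate_cohort("HEALTHY-like", 2, seed=3)[0].truth16


@pytest.fixture
def constant8_study():
    """Noise-free constant 8 mm contour phantom study."""
    spec = lt.PhantomSpec(thickness_profile=lt.constant_profile(8.0))
    return lt.generate_phantom(spec, seed=1)


@pytest.fixture
def half_circle_pair():
    """Concentric half-circle annulus: endo r=20 mm, epi R=28 mm, 600 vertices."""
    th = np.linspace(0.0, np.pi, 600)
    endo = lt.ContourPolyline(np.column_stack([20 * np.cos(th), 20 * np.sin(th)]))
    epi = lt.ContourPolyline(np.column_stack([28 * np.cos(th), 28 * np.sin(th)]))
    return lt.LAXContourPair(plane_id="A2C", endo=endo, epi=epi)


def planted_sequence(n, run_start, run_len, fill=7.0, low=0.1):
    """Sequence of `fill` mm with a planted near-zero run."""
    v = np.full(n, fill)
    v[run_start:run_start + run_len] = low
    return lt.DistanceSequence(plane_id="A2C", values=v)
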