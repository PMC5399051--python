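import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_configuration(rng, k=15, spread=1.0):
    """A generic non-degenerate landmark configuration."""
    while True:
        pts = rng.uniform(-spread, spread, size=(k, 2))
        centred = pts - pts.mean(axis=0)
        svals = np.linalg.svd(centred, compute_uv=False)
        if svals[1] > 1e-3 * svals[0]:
            return pts


def aligned_subspace_instance(seed=42, k=4, n_per_class=10, classes="ABC",
                              shift_sd=0.06, within_sd=0.02):
    """Small aligned-shape instance living exactly in the 2k-4 shape subspace.

    Class means and within-class noise are drawn in the tangent subspace at a
    fixed reference, so the pooled covariance has a clean rank of 2k-4 and
    dense pseudo-inverse oracles see exactly the same space as the model.
    Returns ``(X, labels, reference)``.
    """
    from wingid._geometry import preshape
    from wingid.synthetic_wings import BASE_WING, shape_subspace

    ref = preshape(BASE_WING[:k])
    basis = shape_subspace(ref)
    d = basis.shape[1]
    gen = np.random.default_rng(seed)
    shifts = {lab: shift_sd * gen.standard_normal(d) for lab in classes}
    labels = [lab for lab in classes for _ in range(n_per_class)]
    X = np.array(
        [ref.reshape(-1) + basis @ (shifts[lab] + within_sd * gen.standard_normal(d))
         for lab in labels]
    )
    return X, labels, ref


@pytest.fixture
def small_labelled_shapes():
    """4-landmark aligned shapes in 3 classes of 10, for dense-algebra oracles."""
    return aligned_subspace_instance()
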