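import numpy as np
import pytest

from boldwct import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 4-group multi-site cohort with planted effects (8 nodes)."""
    spec = CohortSpec(
        n_per_group=6,
        n_nodes=8,
        n_timepoints=145,
        planted_node=3,
        partner_nodes=(4, 5, 6),
        rng_seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def binary_signals():
    """Two 145-point signals sharing a 40 s oscillation plus noise."""
    t = np.arange(145) * 2.0
    rng = np.random.default_rng(5)
    phase = rng.uniform(0, 2 * np.pi)
    x = np.sin(2 * np.pi * t / 40 + phase) + 0.5 * rng.normal(size=145)
    y = np.sin(2 * np.pi * t / 40 + phase + 0.8) + 0.5 * rng.normal(size=145)
    return x, y


def separable_images(n_per_class, size, n_classes=2, seed=0):
    """Image stacks whose mean intensity encodes the class (clearly separable)."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in range(n_classes):
        base = (cls + 1) / (n_classes + 1)
        img = np.clip(
            base + 0.08 * rng.normal(size=(n_per_class, size, size, 3)), 0, 1
        )
        xs.append(img)
        ys.append(np.full(n_per_class, cls))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    order = rng.permutation(x.shape[0])
    return x[order], y[order]
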