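"""Shared fixtures: hand-checkable probability tables and frozen test designs."""

import numpy as np
import pytest

from ivbounds import DGPSpec, PiPair
from ivbounds.simulate import class_pipair


@pytest.fixture(scope="session")
def complier_pi() -> PiPair:
    """Deterministic-complier stratum of the motivating design.

    Z=1 arm: everyone exposed, Y ~ Bern(0.35); Z=0 arm: unexposed,
    Y ~ Bern(0.25).  Bounds collapse to the stratum effect 0.10.
    """
    return class_pipair((0, 1), (0.25, 0.35))


@pytest.fixture(scope="session")
def always_taker_pi() -> PiPair:
    """Always-taker stratum: A=1 in both arms, Y ~ Bern(0.30)."""
    return class_pipair((1, 1), (0.20, 0.30))


def make_mixed_binary_spec() -> DGPSpec:
    """Two-stratum binary design mixing all four compliance classes.

    Chosen so every stratum has strictly unique arg-extrema (margin gaps
    >= 0.085), making it suitable for direct-vs-smoothed agreement checks.
    """
    return DGPSpec(
        stratum_masses=[0.6, 0.4],
        class_probs=[[0.15, 0.1, 0.05, 0.7], [0.3, 0.2, 0.1, 0.4]],
        outcome_means=[
            [[0.2, 0.3], [0.85, 0.9], [0.6, 0.7], [0.3, 0.45]],
            [[0.25, 0.4], [0.7, 0.8], [0.55, 0.6], [0.35, 0.5]],
        ],
    )


@pytest.fixture(scope="session")
def mixed_binary_spec() -> DGPSpec:
    return make_mixed_binary_spec()


def make_continuous_spec() -> DGPSpec:
    """Two-stratum bounded-continuous (Beta) outcome design.

    Fixed so that (i) the true ATE (~0.235) sits well inside the integrated
    interval, and (ii) the grid-integrated interval is strictly inside the
    uniform-augmentation interval (gap ~0.02 per side), so the containment
    direction of the two constructions is actually exercised.
    """
    return DGPSpec(
        stratum_masses=[0.5, 0.5],
        class_probs=[[0.1097, 0.0140, 0.1188, 0.7575],
                     [0.3284, 0.0633, 0.4559, 0.1524]],
        outcome_means=[
            [[0.299, 0.550], [0.754, 0.950], [0.825, 0.950], [0.193, 0.454]],
            [[0.735, 0.950], [0.163, 0.353], [0.116, 0.388], [0.519, 0.663]],
        ],
        outcome="beta",
        conc=5.0,
    )


@pytest.fixture(scope="session")
def continuous_spec() -> DGPSpec:
    return make_continuous_spec()


def make_small_gap_dist():
    """Discrete 3-stratum instance with margin gaps ~0.004-0.02 on both sides.

    Near-uniform response-type mixtures: gaps this small keep the strict part
    of the smoothing sandwich (extremum < smoothed value) representable in
    double precision even at temperature 1,000, where large-gap instances
    collapse to exact equality by underflow.
    """
    import numpy as np
    from ivbounds import DiscreteIVDistribution, observables_from_types

    strata = []
    for seed, mass in ((0, 0.5), (19, 0.3), (31, 0.2)):
        rng = np.random.default_rng(seed)
        q = 0.95 * np.full(16, 1 / 16) + 0.05 * rng.dirichlet(np.ones(16))
        strata.append((mass, observables_from_types(q)))
    return DiscreteIVDistribution(strata=tuple(strata), lambda1=0.5)


def random_feasible_pipair(rng: np.random.Generator) -> PiPair:
    """A PiPair guaranteed compatible with the IV model (built from types)."""
    from ivbounds import observables_from_types

    return observables_from_types(rng.dirichlet(np.ones(16)))
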