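"""Generator for experiment-like synapse-count datasets.

The published experimental histograms (a dominant point mass at zero plus a
second peak at 3-8 synapses, sampled from a few dozen neuron pairs) are not
available as numbers, so tests and examples use synthetic stand-ins drawn
from a ground-truth mixture of a zero point mass and a discretized bump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from multisyn.fit_stats import ExperimentData
from multisyn.markov_structural import SynapseDistribution

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of the synthetic ground-truth histogram.

    ``zero_mass`` is the probability of the unconnected state (published
    experiments range from 0.75 to 0.99); the connected part is a
    discretized Gaussian bump centred between 3 and 8 synapses.
    """

    zero_mass: float = 0.9
    center: float = 5.0
    spread: float = 1.5
    n_exp: int = 30
    P_max: int = 12
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.zero_mass <= 1.0):
            raise ValueError("zero_mass must lie in [0, 1]")
        if not (1 <= self.center <= self.P_max):
            raise ValueError("center must lie within [1, P_max]")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.n_exp < 1:
            raise ValueError("n_exp must be >= 1")


def generate_fixture(spec: FixtureSpec):
    """Ground-truth distribution plus an ``n_exp``-sample experiment from it.

    Returns ``(truth, experiment)`` where ``truth`` is the exact mixture
    distribution and ``experiment`` a multinomial sample of size
    ``spec.n_exp`` from it.
    """
    S = np.arange(spec.P_max + 1, dtype=float)
    bump = np.exp(-0.5 * ((S - spec.center) / spec.spread) ** 2)
    bump[0] = 0.0
    if spec.zero_mass < 1.0:
        bump = bump / bump.sum() * (1.0 - spec.zero_mass)
    else:
        bump[:] = 0.0
    p = bump.copy()
    p[0] = spec.zero_mass
    truth = SynapseDistribution(p=p, meta={"method": "fixture", "spec": repr(spec)})

    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_exp, truth.p)
    experiment = ExperimentData(
        freqs=counts / spec.n_exp, n_exp=spec.n_exp, label="synthetic-fixture"
    )
    return truth, experiment
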