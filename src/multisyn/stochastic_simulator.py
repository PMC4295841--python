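"""Time-stepped stochastic simulation of one connection and the hysteresis protocol.

One structural step performs, in order: (1) update the postsynaptic rate
from the IO curve, (2) advance every synaptic weight by one RK4 step of the
plasticity rule, (3) delete each synapse independently with its
weight-dependent probability, (4) create synapses at the sites that were
vacant at the start of the step.

Two execution modes exist:

* the *full* mode keeps an explicit weight per synapse (``step_connection``);
* the *pinned* mode exploits the separation of time scales and keeps the
  weights at their per-``S`` fixed points, which reduces the dynamics to a
  pure Markov chain on the synapse count.  The pinned inner loops are
  numba-compiled and handle the long runs needed for occupancy statistics
  and hysteresis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from multisyn.markov_structural import (
    StructuralParams,
    SynapseDistribution,
    deletion_prob,
    pdel_profile,
)
from multisyn.neuron_core import (
    FeedbackSpec,
    IOCurve,
    SystemPoint,
    activity_profile,
)
from multisyn.rate_rules import RuleSpec, rule_rhs

__all__ = [
    "SimConfig",
    "ConnectionState",
    "HysteresisProtocol",
    "HysteresisTrace",
    "default_w_init",
    "step_connection",
    "run_equilibrium_sim",
    "pinned_occupancy",
    "run_hysteresis",
]


def default_w_init(rule: RuleSpec, reading: str = "kappa") -> float:
    """Initial weight of a newly created synapse.

    The published formula ``0.05 * kappa * (1 - v_tss)**(-1/2)`` is
    typographically ambiguous in whether the prefactor multiplies ``kappa``
    or ``sqrt(kappa)``; both readings are offered (``reading='kappa'`` is
    the literal default, ``reading='sqrt-kappa'`` the alternative).
    """
    if reading == "kappa":
        return 0.05 * rule.kappa / math.sqrt(1.0 - rule.v_tss)
    if reading == "sqrt-kappa":
        return 0.05 * math.sqrt(rule.kappa / (1.0 - rule.v_tss))
    raise ValueError("reading must be 'kappa' or 'sqrt-kappa'")


@dataclass(frozen=True)
class SimConfig:
    """Simulation bookkeeping: length, seed, initial weight, burn-in."""

    n_steps: int
    seed: int = 0
    w_init: float = None  # type: ignore[assignment]
    rk4_substeps: int = 1
    record_stride: int = 1
    burn_in_fraction: float = 0.1

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.w_init is not None and self.w_init <= 0:
            raise ValueError("w_init must be positive")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must lie in [0, 1)")


@dataclass
class ConnectionState:
    """Realised synapses of one connection: weights and current rate."""

    weights: np.ndarray
    v_i: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.weights = w

    @property
    def S(self) -> int:
        return len(self.weights)


def _rk4_weight(rule: RuleSpec, w: float, v_i: float, v_j: float, dt: float) -> float:
    k1 = rule_rhs(rule, w, v_i, v_j)
    k2 = rule_rhs(rule, w + 0.5 * dt * k1, v_i, v_j)
    k3 = rule_rhs(rule, w + 0.5 * dt * k2, v_i, v_j)
    k4 = rule_rhs(rule, w + dt * k3, v_i, v_j)
    w_new = w + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    if rule.kind in ("hebb_hard", "bcm_fixed_hard"):
        w_new = min(max(w_new, rule.w_min), rule.w_max)
    return max(w_new, 0.0)


def step_connection(
    state: ConnectionState,
    sp: StructuralParams,
    rule: RuleSpec,
    io: IOCurve,
    point: SystemPoint,
    rng: np.random.Generator,
    fb: FeedbackSpec | None = None,
    w_init: float = None,  # type: ignore[assignment]
    rk4_substeps: int = 1,
) -> ConnectionState:
    """Advance the connection by one structural step (rates, RK4, delete, build).

    Deletion draws use the weights *after* the RK4 update of the same step;
    creation fills sites that were vacant at the start of the step.  Draws
    are consumed in a fixed order (deletions by ascending synapse index,
    then creations) for reproducibility.
    """
    if w_init is None:
        w_init = default_w_init(rule)
    S0 = state.S
    I = point.current(io)
    w_sum = float(np.sum(state.weights))

    # (1) rate from the IO curve
    if fb is None or fb.r1 == 0:
        vj = point.v_j if fb is None else fb.r0
        v_i = float(io.forward(w_sum * vj + I))
    else:
        # feedback: v_j depends on v_i; resolve the rate by fixed-point iteration
        v_i = float(io.forward(I))
        for _ in range(200):
            vj = float(fb.presynaptic_rate(v_i))
            v_new = float(io.forward(w_sum * vj + I))
            if abs(v_new - v_i) < 1e-12:
                break
            v_i = v_new
        vj = float(fb.presynaptic_rate(v_i))

    # (2) RK4 weight update at the frozen rate
    dt = 1.0 / rk4_substeps
    new_w = state.weights.copy()
    for k in range(S0):
        w = new_w[k]
        for _ in range(rk4_substeps):
            w = _rk4_weight(rule, w, v_i, vj, dt)
        new_w[k] = w

    # (3) weight-dependent deletion
    if S0:
        pdel = deletion_prob(sp, new_w)
        pdel = np.atleast_1d(pdel)
        keep = rng.random(S0) >= pdel
        new_w = new_w[keep]

    # (4) creation at sites vacant at the start of the step
    n_vacant = sp.P - S0
    n_new = rng.binomial(n_vacant, sp.p_build_eff) if n_vacant > 0 else 0
    if n_new:
        new_w = np.concatenate([new_w, np.full(n_new, w_init)])

    return ConnectionState(weights=new_w, v_i=v_i)


def run_equilibrium_sim(
    config: SimConfig,
    sp: StructuralParams,
    rule: RuleSpec,
    io: IOCurve,
    point: SystemPoint,
    fb: FeedbackSpec | None = None,
    record_trace: bool = False,
):
    """Occupancy histogram of the synapse count over a full simulation.

    The first ``burn_in_fraction`` of the steps is discarded.  Returns the
    empirical :class:`SynapseDistribution` (and the recorded trace when
    ``record_trace`` is set: array of (step, S, mean_w, v_i) rows).
    """
    rng = np.random.default_rng(config.seed)
    state = ConnectionState(weights=np.empty(0))
    counts = np.zeros(sp.P + 1, dtype=np.int64)
    burn_in = int(config.burn_in_fraction * config.n_steps)
    trace = []
    for step in range(config.n_steps):
        state = step_connection(state, sp, rule, io, point, rng, fb,
                                w_init=config.w_init, rk4_substeps=config.rk4_substeps)
        if step >= burn_in:
            counts[state.S] += 1
        if record_trace and step % config.record_stride == 0:
            mean_w = float(state.weights.mean()) if state.S else 0.0
            trace.append((step, state.S, mean_w, state.v_i))
    dist = SynapseDistribution(
        p=counts / counts.sum(),
        meta={"method": "simulation", "n_steps": config.n_steps, "seed": config.seed},
    )
    if record_trace:
        return dist, np.array(trace)
    return dist


# ---------------------------------------------------------------------------
# pinned-weight (timescale-separated) fast paths
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pinned_chain(n_steps, P, pdel_by_S, p_build, S0, burn_in, seed):
    np.random.seed(seed)
    counts = np.zeros(P + 1, dtype=np.int64)
    S = S0
    for step in range(n_steps):
        d = np.random.binomial(S, pdel_by_S[S]) if S > 0 else 0
        b = np.random.binomial(P - S, p_build) if S < P else 0
        S = S - d + b
        if step >= burn_in:
            counts[S] += 1
    return counts


def pinned_occupancy(
    config: SimConfig,
    sp: StructuralParams,
    pdel_by_S: np.ndarray,
    S0: int = 0,
) -> SynapseDistribution:
    """Long-run occupancy of the synapse-count chain with pinned weights.

    The weights are held at their per-``S`` fixed points (``pdel_by_S``
    precomputed from an activity profile), so each step reduces to two
    binomial draws.  Equivalent to sampling from the transition matrix.
    """
    pdel = np.asarray(pdel_by_S, dtype=float)
    if pdel.shape != (sp.P + 1,):
        raise ValueError(f"pdel_by_S must have length {sp.P + 1}")
    burn_in = int(config.burn_in_fraction * config.n_steps)
    counts = _pinned_chain(config.n_steps, sp.P, pdel, sp.p_build_eff,
                           S0, burn_in, config.seed)
    return SynapseDistribution(
        p=counts / counts.sum(),
        meta={"method": "pinned-simulation", "n_steps": config.n_steps, "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# hysteresis protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HysteresisProtocol:
    """Triangular stimulation protocol for one of the two sides.

    The stimulation level (presynaptic rate, or baseline postsynaptic rate
    ``v_i(S=0)``) is stepped from ``lower`` to ``upper`` and back in
    increments of ``step``; each level is held for ``dwell`` structural
    steps and the whole cycle is repeated ``n_cycles`` times.
    """

    varied: str = "post"  # 'pre' | 'post'
    step: float = 0.01
    upper: float = 1.0
    lower: float = 0.05
    dwell: int = 10_000
    n_cycles: int = 20

    def __post_init__(self):
        if self.varied not in ("pre", "post"):
            raise ValueError("varied must be 'pre' or 'post'")
        if not (0.0 < self.lower < self.upper <= 1.0):
            raise ValueError("need 0 < lower < upper <= 1")
        if self.dwell < 1 or self.n_cycles < 1:
            raise ValueError("dwell and n_cycles must be >= 1")

    @property
    def levels(self) -> np.ndarray:
        n = int(round((self.upper - self.lower) / self.step))
        return self.lower + self.step * np.arange(n + 1)


@dataclass(frozen=True)
class HysteresisTrace:
    """Cycle-averaged mean synapse count per level, per sweep direction."""

    levels: np.ndarray
    mean_up: np.ndarray
    mean_down: np.ndarray
    per_cycle_up: np.ndarray  # shape (n_cycles, n_levels)
    per_cycle_down: np.ndarray
    varied: str = "post"

    def loop_area(self) -> float:
        return float(np.trapezoid(self.mean_down - self.mean_up, self.levels))


@njit(cache=True)
def _hysteresis_run(pdel_levels, p_build, P, dwell, n_cycles, seed):
    """Triangular sweep over precomputed per-level deletion profiles."""
    np.random.seed(seed)
    n_levels = pdel_levels.shape[0]
    sum_up = np.zeros((n_cycles, n_levels))
    sum_down = np.zeros((n_cycles, n_levels))
    S = 0
    for cycle in range(n_cycles):
        for direction in range(2):
            for idx in range(n_levels):
                li = idx if direction == 0 else n_levels - 1 - idx
                acc = 0.0
                for _ in range(dwell):
                    d = np.random.binomial(S, pdel_levels[li, S]) if S > 0 else 0
                    b = np.random.binomial(P - S, p_build) if S < P else 0
                    S = S - d + b
                    acc += S
                if direction == 0:
                    sum_up[cycle, li] = acc / dwell
                else:
                    sum_down[cycle, li] = acc / dwell
    return sum_up, sum_down


def run_hysteresis(
    protocol: HysteresisProtocol,
    config: SimConfig,
    sp: StructuralParams,
    rule: RuleSpec,
    io: IOCurve,
    fixed_value: float,
    fb: FeedbackSpec | None = None,
) -> HysteresisTrace:
    """Simulate the triangular stimulation protocol and average per level.

    ``fixed_value`` is the constant value of the side that is *not* varied
    (``v_j`` when sweeping the postsynaptic level, the baseline rate
    ``v_i(S=0)`` when sweeping the presynaptic one).

    The run uses the pinned-weight mode: for every level the consistent
    per-``S`` deletion probabilities are precomputed, after which the sweep
    is a pure Markov chain.  Levels whose activity profile is unsolvable for
    some ``S`` fall back to the nearest-neighbour level's profile.
    """
    levels = protocol.levels
    pdel_levels = np.empty((len(levels), sp.P + 1))
    ok = np.zeros(len(levels), dtype=bool)
    for i, level in enumerate(levels):
        lv = min(max(level, 1e-9), 1.0 - 1e-9)
        if protocol.varied == "post":
            pt = SystemPoint(v_j=fixed_value, v_i_S0=lv)
        else:
            pt = SystemPoint(v_j=lv, v_i_S0=fixed_value)
        try:
            prof = activity_profile(sp.P, pt, rule, io, fb)
            pdel_levels[i] = pdel_profile(sp, prof)
            ok[i] = True
        except Exception:
            ok[i] = False
    if not ok.any():
        raise RuntimeError("no level of the protocol has a solvable activity profile")
    good = np.flatnonzero(ok)
    for i in np.flatnonzero(~ok):
        pdel_levels[i] = pdel_levels[good[np.argmin(np.abs(good - i))]]

    sum_up, sum_down = _hysteresis_run(
        pdel_levels, sp.p_build_eff, sp.P, protocol.dwell, protocol.n_cycles, config.seed
    )
    return HysteresisTrace(
        levels=levels,
        mean_up=sum_up.mean(axis=0),
        mean_down=sum_down.mean(axis=0),
        per_cycle_up=sum_up,
        per_cycle_down=sum_down,
        varied=protocol.varied,
    )
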