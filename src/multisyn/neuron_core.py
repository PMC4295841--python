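"""Neuron input-output curves and self-consistent activity/weight states.

The postsynaptic rate of the modelled neuron obeys

    v_i = F(S * w * v_j + I)

where ``F`` is a monotone input-output curve, ``S`` the number of realised
synapses, ``w`` the per-synapse weight, ``v_j`` the presynaptic rate and
``I`` the lumped external influence.  Because the weight itself relaxes to a
rule-dependent fixed point ``w*(v_i, v_j)``, the pair ``(v_i*, w*)`` has to
be determined self-consistently for every ``S``; that is the job of
:func:`consistent_state`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, logit

from multisyn.rate_rules import (
    RuleDomainError,
    RuleNotApplicable,
    RuleSpec,
    fixed_weight,
    fixed_weight_array,
)

__all__ = [
    "IOCurve",
    "FeedbackSpec",
    "SystemPoint",
    "ConsistentState",
    "NoRootError",
    "logistic",
    "logistic_inverse",
    "consistent_state",
    "activity_profile",
]


def logistic(x):
    """Logistic input-output curve ``1 / (1 + exp(-x))``."""
    return expit(x)


def logistic_inverse(p):
    """Inverse of :func:`logistic`; rejects arguments outside (0, 1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr >= 1.0):
        raise ValueError("logistic_inverse requires arguments in the open interval (0, 1)")
    return logit(p)


class IOCurve:
    """Strictly increasing input-output curve with an explicit inverse.

    Parameters
    ----------
    forward, inverse:
        Vectorised callables mapping current -> rate and rate -> current.
    x_domain:
        Admissible current interval.
    name:
        Short label used in reports and serialized metadata.
    """

    def __init__(
        self,
        forward: Callable,
        inverse: Callable,
        x_domain: tuple[float, float] = (-np.inf, np.inf),
        name: str = "custom",
    ):
        self._forward = forward
        self._inverse = inverse
        self.x_domain = x_domain
        self.name = name

    def __call__(self, x):
        return self._forward(x)

    def forward(self, x):
        return self._forward(x)

    def inverse(self, p):
        return self._inverse(p)

    def __repr__(self):  # pragma: no cover
        return f"IOCurve({self.name!r})"

    # -- constructors -------------------------------------------------------

    @classmethod
    def logistic(cls) -> "IOCurve":
        return cls(logistic, logistic_inverse, name="logistic")

    @classmethod
    def linear(cls, slope: float, intercept: float, x_domain: tuple[float, float]) -> "IOCurve":
        """Linear curve clipped to rates in [0, 1]; invertible on its domain."""
        if slope <= 0:
            raise ValueError("slope must be positive")

        def fwd(x):
            return np.clip(slope * np.asarray(x, dtype=float) + intercept, 0.0, 1.0)

        def inv(p):
            return (np.asarray(p, dtype=float) - intercept) / slope

        return cls(fwd, inv, x_domain=x_domain, name="linear")

    @classmethod
    def from_samples(cls, x: Sequence[float], y: Sequence[float], name: str = "empirical") -> "IOCurve":
        """Piecewise-linear empirical curve; abscissa must strictly increase."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(np.diff(y) < 0):
            raise ValueError("empirical IO curve must be non-decreasing")

        def fwd(q):
            q = np.asarray(q, dtype=float)
            if np.any(q < x[0]) or np.any(q > x[-1]):
                raise ValueError("input outside empirical curve domain")
            return np.interp(q, x, y)

        def inv(p):
            p = np.asarray(p, dtype=float)
            if np.any(p < y[0]) or np.any(p > y[-1]):
                raise ValueError("rate outside empirical curve range")
            return np.interp(p, y, x)

        return cls(fwd, inv, x_domain=(float(x[0]), float(x[-1])), name=name)


@dataclass(frozen=True)
class FeedbackSpec:
    """Linear dependence of the presynaptic on the postsynaptic rate.

    ``v_j = r0 + r1 * v_i``.  A feed-forward system has ``r1 = 0`` with the
    constant presynaptic rate in ``r0``; the linear-feedback system is
    ``r0 = 0, r1 = 1``.
    """

    r0: float
    r1: float = 0.0

    def __post_init__(self):
        for v in (0.0, 1.0):
            out = self.r0 + self.r1 * v
            if not (-1e-12 <= out <= 1.0 + 1e-12):
                raise ValueError(
                    f"presynaptic rate r0 + r1*v_i = {out:.4g} leaves [0, 1] at v_i = {v}"
                )

    def presynaptic_rate(self, v_i):
        return self.r0 + self.r1 * np.asarray(v_i, dtype=float)

    @classmethod
    def feedforward(cls, v_j: float) -> "FeedbackSpec":
        return cls(r0=v_j, r1=0.0)

    @classmethod
    def linear_feedback(cls) -> "FeedbackSpec":
        return cls(r0=0.0, r1=1.0)


@dataclass(frozen=True)
class SystemPoint:
    """External drive of the two-neuron system.

    Either the postsynaptic influence ``I`` or the equivalent baseline rate
    ``v_i(S=0) = F(I)`` may be given; the other one is derived through the
    IO curve.
    """

    v_j: float
    I: float = None  # type: ignore[assignment]
    v_i_S0: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if not (0.0 <= self.v_j <= 1.0):
            raise ValueError("v_j must lie in [0, 1]")
        if self.I is None and self.v_i_S0 is None:
            raise ValueError("either I or v_i_S0 must be given")

    def current(self, io: IOCurve) -> float:
        if self.I is not None:
            return float(self.I)
        return float(io.inverse(self.v_i_S0))

    def baseline_rate(self, io: IOCurve) -> float:
        if self.v_i_S0 is not None:
            return float(self.v_i_S0)
        return float(io.forward(self.I))

    @classmethod
    def from_baseline(cls, v_j: float, v_i_S0: float) -> "SystemPoint":
        return cls(v_j=v_j, v_i_S0=v_i_S0)


@dataclass(frozen=True)
class ConsistentState:
    """Jointly consistent postsynaptic rate and per-synapse fixed weight."""

    S: float
    v_i: float
    w: float
    residual: float
    all_roots: tuple = field(default_factory=tuple)

    @property
    def multistable(self) -> bool:
        return len(self.all_roots) > 1


class NoRootError(RuntimeError):
    """The self-consistency map has no solution in the evaluable domain."""


_GRID_N = 2000
_RESIDUAL_TOL = 1e-10


def _effective_vj(v, point: SystemPoint, fb: FeedbackSpec | None):
    if fb is None or fb.r1 == 0.0:
        vj = point.v_j if fb is None else fb.r0
        return np.full_like(np.asarray(v, dtype=float), vj)
    return fb.presynaptic_rate(v)


def _selfcons_gap(v, S, I, rule, io, point, fb):
    """g(v) = F(S * w*(v) * v_j(v) + I) - v, NaN where the rule is undefined."""
    v = np.atleast_1d(np.asarray(v, dtype=float))
    vj = _effective_vj(v, point, fb)
    w = fixed_weight_array(rule, v, vj)
    with np.errstate(over="ignore", invalid="ignore"):
        g = io.forward(S * w * vj + I) - v
    return g, w


def _gap_scalar(v, S, I, rule, io, point, fb):
    """Scalar, allocation-free version of :func:`_selfcons_gap` for bisection."""
    if fb is None or fb.r1 == 0.0:
        vj = point.v_j if fb is None else fb.r0
    else:
        vj = fb.r0 + fb.r1 * v
    try:
        w = fixed_weight(rule, v, vj)
    except (RuleDomainError, RuleNotApplicable):
        return float("nan")
    return float(io.forward(S * w * vj + I)) - v


def _forward_iterate(S, I, rule, io, point, fb, v0, n_iter=400):
    """Iterate v <- F(S w*(v) v_j + I); used only to pick among multiple roots."""
    v = float(v0)
    for _ in range(n_iter):
        vj = float(_effective_vj(v, point, fb)[()] if np.isscalar(v) else _effective_vj(v, point, fb))
        try:
            w = fixed_weight(rule, v, vj)
        except RuleDomainError:
            # no fixed weight here: the weight grows without bound, pushing the
            # rate upwards -- continue from just above the undefined interval
            v = min(1.0 - 1e-9, v + 1e-3)
            continue
        v_new = float(io.forward(S * w * vj + I))
        if abs(v_new - v) < 1e-13:
            return v_new
        v = min(max(v_new, 1e-12), 1.0 - 1e-12)
    return v


def consistent_state(
    S: float,
    point: SystemPoint,
    rule: RuleSpec,
    io: IOCurve,
    fb: FeedbackSpec | None = None,
    grid_n: int = _GRID_N,
) -> ConsistentState:
    """Solve ``v = F(S * w*(v) * v_j(v) + I)`` for the state with ``S`` synapses.

    The unit rate interval is scanned on a uniform grid for sign changes of
    the self-consistency gap, each bracket is bisected, and -- should several
    roots exist -- the one reached by forward iteration from the baseline
    rate ``F(I)`` is returned.  All roots are exposed on the result.

    Raises
    ------
    NoRootError
        If no solution exists in the evaluable part of (0, 1).
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    I = point.current(io)

    if S == 0:
        v0 = float(io.forward(I))
        vj0 = float(np.asarray(_effective_vj(v0, point, fb)).reshape(-1)[0])
        try:
            w0 = float(fixed_weight(rule, v0, vj0))
        except RuleDomainError:
            w0 = float("nan")  # no synapse exists; the weight is moot
        return ConsistentState(S=0, v_i=v0, w=w0, residual=0.0, all_roots=(v0,))

    # extra end points catch roots in the saturated tails of the IO curve
    vs = np.concatenate(
        ([1e-15], np.linspace(1e-9, 1.0 - 1e-9, grid_n), [1.0 - 1e-15])
    )
    g, _ = _selfcons_gap(vs, S, I, rule, io, point, fb)
    valid = np.isfinite(g)

    roots = []
    # exact zeros on the grid
    exact = np.flatnonzero(valid & (g == 0.0))
    roots.extend(float(vs[i]) for i in exact)
    sign_change = (
        valid[:-1]
        & valid[1:]
        & (np.sign(g[:-1]) * np.sign(g[1:]) < 0)
    )
    for i in np.flatnonzero(sign_change):
        lo, hi = float(vs[i]), float(vs[i + 1])
        glo = float(g[i])
        for _ in range(55):
            mid = 0.5 * (lo + hi)
            gm = _gap_scalar(mid, S, I, rule, io, point, fb)
            if not math.isfinite(gm) or gm == 0.0:
                lo = hi = mid
                break
            if (gm > 0) == (glo > 0):
                lo, glo = mid, gm
            else:
                hi = mid
        roots.append(0.5 * (lo + hi))

    if not roots:
        # IO curve saturated in floating point: the root sits within one ulp
        # of a boundary; recover it by fixed-point iteration from that side
        for start, cond in ((1.0, np.isfinite(g[-1]) and g[-1] > 0),
                            (1e-15, np.isfinite(g[0]) and g[0] < 0)):
            if not cond:
                continue
            v = start
            for _ in range(100):
                gv = _gap_scalar(v, S, I, rule, io, point, fb)
                if not math.isfinite(gv):
                    break
                v_new = gv + v
                if abs(v_new - v) < 1e-16:
                    break
                v = v_new
            if math.isfinite(_gap_scalar(v, S, I, rule, io, point, fb)):
                roots.append(v)
                break
    if not roots:
        raise NoRootError(f"no self-consistent rate for S={S} at I={I:.4g}")
    roots = sorted(set(round(r, 14) for r in roots))

    if len(roots) == 1:
        v_star = roots[0]
    else:
        v_start = float(io.forward(I))
        v_iter = _forward_iterate(S, I, rule, io, point, fb, v_start)
        v_star = min(roots, key=lambda r: abs(r - v_iter))

    vj = float(np.asarray(_effective_vj(v_star, point, fb)).reshape(-1)[0])
    w_star = float(fixed_weight(rule, v_star, vj))
    residual = abs(float(io.forward(S * w_star * vj + I)) - v_star)
    if residual > max(_RESIDUAL_TOL, 1e-8):
        raise NoRootError(
            f"self-consistency residual {residual:.3g} too large for S={S}"
        )
    return ConsistentState(S=float(S), v_i=v_star, w=w_star, residual=residual, all_roots=tuple(roots))


@dataclass(frozen=True)
class ActivityProfile:
    """Per-``S`` consistent states for ``S = 0 ... P``."""

    states: tuple
    monotone: bool
    failures: tuple = field(default_factory=tuple)

    @property
    def v_i(self) -> np.ndarray:
        return np.array([s.v_i for s in self.states])

    @property
    def w(self) -> np.ndarray:
        return np.array([s.w for s in self.states])

    def __iter__(self):
        return iter(self.states)

    def __len__(self):
        return len(self.states)


def activity_profile(
    P: int,
    point: SystemPoint,
    rule: RuleSpec,
    io: IOCurve,
    fb: FeedbackSpec | None = None,
    strict: bool = True,
) -> ActivityProfile:
    """Batch :func:`consistent_state` over ``S = 0 ... P``.

    With ``strict=True`` any per-``S`` failure raises immediately; otherwise
    failures are collected on the returned profile (states list then skips
    the failing ``S``).
    """
    states, failures = [], []
    for S in range(int(P) + 1):
        try:
            states.append(consistent_state(S, point, rule, io, fb))
        except (NoRootError, RuleDomainError) as exc:
            if strict:
                raise NoRootError(f"S={S}: {exc}") from exc
            failures.append((S, str(exc)))
    v = [s.v_i for s in states]
    monotone = all(b >= a - 1e-12 for a, b in zip(v, v[1:]))
    return ActivityProfile(states=tuple(states), monotone=monotone, failures=tuple(failures))
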