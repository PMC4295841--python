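"""Rate-based synaptic plasticity rules, their fixed weights and condition checkers.

Each rule is a differential equation ``dw/dt = rhs(w, v_i, v_j)`` with a
stable fixed point ``w*(v_i, v_j)``.  Two qualitative checks are provided:

* :func:`necessary_condition` -- does the fixed weight grow with the
  postsynaptic rate?  Only then can the synapse-count distribution develop
  the experimentally observed second peak.
* :func:`sufficient_condition` -- is the average curvature of the
  log-probability increment between its two zero crossings negative, i.e.
  do the extrema appear in the order (valley, peak)?
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

__all__ = [
    "RuleSpec",
    "RuleDomainError",
    "RuleNotApplicable",
    "RULE_KINDS",
    "rule_rhs",
    "fixed_weight",
    "integrate_to_fixed_weight",
    "necessary_condition",
    "sufficient_condition",
    "ConditionReport",
    "CurvatureReport",
]

RULE_KINDS = (
    "hebb_hard",
    "bcm_fixed_hard",
    "bcm_sliding",
    "oja",
    "hebb_scaling",
    "bcm_scaling",
    "linear_vw",
    "empirical",
)


class RuleDomainError(ValueError):
    """The rule has no admissible fixed weight at the given activities."""


class RuleNotApplicable(ValueError):
    """The fixed weight cannot be evaluated without extra system knowledge."""


@dataclass(frozen=True)
class RuleSpec:
    """One synaptic plasticity rule plus its parameters.

    Parameters
    ----------
    kind:
        One of :data:`RULE_KINDS`.
    mu:
        Learning rate (per time step).
    theta:
        LTP/LTD threshold of the BCM-type rules.
    kappa:
        Scaling-influence parameter of the synaptic-scaling terms.
    v_tss:
        Target rate of synaptic scaling.
    w_min, w_max:
        Hard weight bounds where the rule uses them.
    theta_tilde:
        Sliding-threshold coefficient (``theta = theta_tilde * v_i**2``).
    w_fixed:
        Externally imposed fixed weight for the sliding-threshold rule when
        no assumption about the inverse IO curve is made.
    lin0, lin1:
        Coefficients of the synthetic linear v-w relation (``linear_vw``).
    vw_fn:
        Callable ``(v_i, v_j) -> w*`` for empirically tabulated rules such
        as the calcium-based one.
    """

    kind: str
    mu: float = 0.2
    theta: float = 0.08
    kappa: float = 9.0
    v_tss: float = 0.1
    w_min: float = 0.0
    w_max: float = 1.0
    theta_tilde: float = None  # type: ignore[assignment]
    w_fixed: float = None  # type: ignore[assignment]
    lin0: float = 0.0
    lin1: float = 1.0
    vw_fn: Callable = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0.0 < self.v_tss < 1.0):
            raise ValueError("v_tss must lie in (0, 1)")
        if self.w_min < 0 or self.w_min >= self.w_max:
            raise ValueError("need 0 <= w_min < w_max")

    def with_(self, **kw) -> "RuleSpec":
        return replace(self, **kw)


def rule_rhs(rule: RuleSpec, w: float, v_i: float, v_j: float) -> float:
    """Time derivative of the weight under ``rule`` (before hard bounds)."""
    k = rule.kind
    if k == "hebb_hard":
        return rule.mu * v_j * v_i
    if k == "bcm_fixed_hard":
        return rule.mu * v_j * v_i * (v_i - rule.theta)
    if k == "bcm_sliding":
        if rule.theta_tilde is None:
            raise RuleNotApplicable("bcm_sliding requires theta_tilde for its dynamics")
        return rule.mu * v_j * v_i * (v_i - rule.theta_tilde * v_i**2)
    if k == "oja":
        return rule.mu * (v_j * v_i - w * v_i**2)
    if k == "hebb_scaling":
        return rule.mu * (v_j * v_i - (v_i - rule.v_tss) * w**2 / rule.kappa)
    if k == "bcm_scaling":
        return rule.mu * (
            v_j * v_i * (v_i - rule.theta) - (v_i - rule.v_tss) * w**2 / rule.kappa
        )
    if k == "linear_vw":
        return rule.mu * (rule.lin0 + rule.lin1 * v_i - w)
    if k == "empirical":
        if rule.vw_fn is None:
            raise RuleNotApplicable("empirical rule requires vw_fn")
        return rule.mu * (rule.vw_fn(v_i, v_j) - w)
    raise ValueError(f"unknown rule kind {k!r}")  # pragma: no cover


def _scaling_fixed_weight(hebb: float, scale: float, kappa: float) -> float:
    """Stable fixed weight of ``mu * (hebb - scale * w^2 / kappa)`` under w >= 0.

    ``scale = v_i - v_tss``.  The stable solutions are:

    * ``hebb > 0, scale > 0``: the positive root ``sqrt(kappa*hebb/scale)``.
    * ``hebb < 0, scale < 0``: the drift at small ``w`` is negative, so the
      weight collapses onto the reflecting bound at zero (the positive root
      of the closed form exists but is unstable).
    * ``hebb <= 0 < scale``: the closed form requires the square root of a
      negative number -- reported as a domain error rather than clamped.
    * ``hebb > 0 > scale``: the drift is positive for every weight; no
      fixed point exists.
    """
    if hebb > 0.0 and scale > 0.0:
        return math.sqrt(kappa * hebb / scale)
    if hebb == 0.0 and scale != 0.0:
        return 0.0 if scale > 0.0 else 0.0
    if hebb < 0.0 and scale < 0.0:
        return 0.0
    if scale == 0.0:
        raise RuleDomainError("scaling term vanishes at v_i = v_tss; no finite fixed weight")
    raise RuleDomainError(
        f"no admissible fixed weight (hebbian drive {hebb:.3g}, scaling factor {scale:.3g})"
    )


def fixed_weight(rule: RuleSpec, v_i: float, v_j: float, io=None, I: float = None) -> float:
    """Stable fixed point of :func:`rule_rhs` at the given activities.

    Hard-bounded rules return the admissible bound.  The sliding-threshold
    BCM rule needs either an externally imposed ``w_fixed`` or an invertible
    IO curve together with the postsynaptic influence ``I``.
    """
    k = rule.kind
    if k == "hebb_hard":
        return rule.w_max
    if k == "bcm_fixed_hard":
        return rule.w_max if v_i > rule.theta else rule.w_min
    if k == "bcm_sliding":
        if rule.w_fixed is not None:
            return rule.w_fixed
        if rule.theta_tilde is None or io is None or I is None:
            raise RuleNotApplicable(
                "bcm_sliding fixed weight needs w_fixed, or theta_tilde with io and I"
            )
        v_star = 1.0 / rule.theta_tilde
        if v_j <= 0:
            raise RuleDomainError("bcm_sliding fixed weight undefined for v_j <= 0")
        return (float(io.inverse(v_star)) - I) / v_j
    if k == "oja":
        if v_i <= 0:
            raise RuleDomainError("oja fixed weight undefined for v_i <= 0")
        return v_j / v_i
    if k == "hebb_scaling":
        return _scaling_fixed_weight(v_j * v_i, v_i - rule.v_tss, rule.kappa)
    if k == "bcm_scaling":
        return _scaling_fixed_weight(
            v_j * v_i * (v_i - rule.theta), v_i - rule.v_tss, rule.kappa
        )
    if k == "linear_vw":
        return rule.lin0 + rule.lin1 * v_i
    if k == "empirical":
        if rule.vw_fn is None:
            raise RuleNotApplicable("empirical rule requires vw_fn")
        return float(rule.vw_fn(v_i, v_j))
    raise ValueError(f"unknown rule kind {k!r}")  # pragma: no cover


def fixed_weight_array(rule: RuleSpec, v_i: np.ndarray, v_j: np.ndarray) -> np.ndarray:
    """Vectorised :func:`fixed_weight`; NaN where no admissible fixed point exists.

    Semantically identical to the scalar version for the closed-form kinds
    (domain errors become NaN); the empirical kind falls back to a guarded
    loop.  Used by the self-consistency grid scan.
    """
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    k = rule.kind
    if k == "hebb_hard":
        return np.full_like(v_i, rule.w_max)
    if k == "bcm_fixed_hard":
        return np.where(v_i > rule.theta, rule.w_max, rule.w_min)
    if k == "bcm_sliding":
        if rule.w_fixed is None:
            raise RuleNotApplicable("bcm_sliding array evaluation needs w_fixed")
        return np.full_like(v_i, rule.w_fixed)
    if k == "oja":
        with np.errstate(divide="ignore", invalid="ignore"):
            w = v_j / v_i
        return np.where(v_i > 0, w, np.nan)
    if k in ("hebb_scaling", "bcm_scaling"):
        hebb = v_j * v_i if k == "hebb_scaling" else v_j * v_i * (v_i - rule.theta)
        scale = v_i - rule.v_tss
        w = np.full_like(v_i, np.nan)
        pos = (hebb > 0) & (scale > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w[pos] = np.sqrt(rule.kappa * hebb[pos] / scale[pos])
        w[(hebb < 0) & (scale < 0)] = 0.0
        w[(hebb == 0) & (scale != 0)] = 0.0
        return w
    if k == "linear_vw":
        return rule.lin0 + rule.lin1 * v_i
    out = np.full_like(v_i, np.nan)
    for idx in np.ndindex(v_i.shape):
        try:
            out[idx] = fixed_weight(rule, float(v_i[idx]), float(v_j[idx]))
        except (RuleDomainError, RuleNotApplicable):
            pass
    return out


def integrate_to_fixed_weight(
    rule: RuleSpec,
    w0: float,
    v_i: float,
    v_j: float,
    dt: float = 0.05,
    n_steps: int = 400_000,
    tol: float = 1e-9,
) -> float:
    """Euler-integrate ``rule_rhs`` at frozen activities until the weight settles.

    Hard-bounded kinds are clamped to their bounds after every step.  Used as
    an independent stability oracle for :func:`fixed_weight`.
    """
    hard = rule.kind in ("hebb_hard", "bcm_fixed_hard")
    lo = rule.w_min
    hi = rule.w_max
    w = float(w0)
    for _ in range(n_steps):
        dw = rule_rhs(rule, w, v_i, v_j) * dt
        w_new = w + dw
        if hard:
            w_new = min(max(w_new, lo), hi)
        elif w_new < 0.0:
            w_new = 0.0
        if abs(w_new - w) < tol * dt:
            return w_new
        w = w_new
    return w


@dataclass(frozen=True)
class ConditionReport:
    """Outcome of :func:`necessary_condition` with the evaluated slope profile."""

    satisfied: bool
    v_grid: np.ndarray
    slope: np.ndarray
    evaluable_fraction: float
    notes: str = ""

    def __bool__(self):
        return self.satisfied


def necessary_condition(
    rule: RuleSpec,
    system,
    v_range: tuple[float, float],
    n_grid: int = 200,
) -> ConditionReport:
    """Check whether ``d w*(v_i) / d v_i > 0`` throughout ``v_range``.

    ``system`` is a :class:`~multisyn.neuron_core.FeedbackSpec`; it supplies
    the presynaptic rate as a function of the postsynaptic one (constant for
    the feed-forward case).  The derivative is taken by central differences
    with step 1e-4; points where the fixed weight is undefined shrink the
    evaluable range and are reported.
    """
    lo, hi = v_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("v_range must satisfy 0 < lo < hi < 1")
    vs = np.linspace(lo, hi, n_grid)
    h = 1e-4
    slope = np.full(n_grid, np.nan)
    for i, v in enumerate(vs):
        try:
            wp = fixed_weight(rule, v + h, float(system.presynaptic_rate(v + h)))
            wm = fixed_weight(rule, v - h, float(system.presynaptic_rate(v - h)))
        except (RuleDomainError, RuleNotApplicable):
            continue
        slope[i] = (wp - wm) / (2 * h)
    evaluable = np.isfinite(slope)
    frac = float(evaluable.mean())
    notes = "" if frac == 1.0 else f"fixed weight undefined on {1 - frac:.0%} of the range"
    ok = bool(frac > 0 and np.all(slope[evaluable] > 0.0))
    return ConditionReport(satisfied=ok, v_grid=vs, slope=slope, evaluable_fraction=frac, notes=notes)


@dataclass(frozen=True)
class CurvatureReport:
    """Outcome of :func:`sufficient_condition`."""

    satisfied: bool
    applicable: bool
    mean_curvature: float
    crossings: tuple
    mechanism: str = ""

    def __bool__(self):
        return self.applicable and self.satisfied


def sufficient_condition(
    rule: RuleSpec,
    io,
    system,
    v_range: tuple[float, float],
    structural=None,
    point=None,
    delta: np.ndarray = None,
) -> CurvatureReport:
    """Mean curvature of the log-probability increment between its zero crossings.

    Either a precomputed increment profile ``delta`` (values for
    ``S = 1 ... P``) is supplied, or ``structural`` and ``point`` are given
    and the profile is computed through the Markov machinery.  Returns a
    not-applicable report when fewer than two zero crossings exist.
    """
    if delta is None:
        if structural is None or point is None:
            raise ValueError("either delta or (structural, point) must be given")
        from multisyn import markov_structural as ms

        nec = necessary_condition(rule, system, v_range)
        if not nec.satisfied:
            return CurvatureReport(
                satisfied=False, applicable=False, mean_curvature=float("nan"),
                crossings=(), mechanism="necessary condition violated",
            )
        from multisyn.neuron_core import activity_profile

        profile = activity_profile(structural.P, point, rule, io, system)
        pdel = ms.pdel_profile(structural, profile)
        delta = ms.delta_ln_p(structural, pdel)
    delta = np.asarray(delta, dtype=float)

    sign = np.sign(delta)
    crossings = [i for i in range(len(sign) - 1) if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]]
    crossings += [i for i in range(len(sign)) if sign[i] == 0]
    crossings = sorted(set(crossings))
    if len(crossings) < 2:
        return CurvatureReport(
            satisfied=False, applicable=False, mean_curvature=float("nan"),
            crossings=tuple(crossings), mechanism="fewer than two zero crossings",
        )
    lo_ix, hi_ix = crossings[0], crossings[-1] + 1
    segment = delta[max(lo_ix - 1, 0): min(hi_ix + 2, len(delta))]
    if len(segment) < 3:
        segment = delta
    curv = np.diff(segment, n=2)
    mean_curv = float(curv.mean()) if curv.size else float("nan")
    satisfied = bool(mean_curv < 0.0)
    mechanism = ""
    if satisfied:
        mechanism = (
            "concave IO curve (case 6_2)" if getattr(io, "name", "") == "logistic"
            else "concave v-w relation (case 6_1)"
        )
    return CurvatureReport(
        satisfied=satisfied, applicable=True, mean_curvature=mean_curv,
        crossings=tuple(crossings), mechanism=mechanism,
    )
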