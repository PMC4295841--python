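"""Birth-death Markov model of the synapse count on one connection.

States are the number of realised synapses ``S = 0 ... P``.  Each vacant
potential site gains a synapse with probability ``p_build`` per step; each
realised synapse is removed with the weight-dependent probability

    p_del(w) = p_build**rho * exp(-a**2 * w**q)

so that strong synapses live longer.  ``rho`` scales the (log) maximum
deletion probability relative to the building probability and ``a`` sets the
weight sensitivity; the exponent ``q`` defaults to 4/3 (spine-volume
dynamics) and is configurable.

Note on the deletion probability
--------------------------------
The source model prints the prefactor ambiguously; with a *product*
``p_build * rho`` the deletion probability could never exceed the building
probability for rho < 1 and no distribution with a dominant peak at S = 0
could ever arise at the published parameters.  Only the *power* reading
``p_build**rho`` reproduces the published working point (second peak between
3 and 8 synapses) and the documented direction of the (a, rho) parameter
sweep, so that reading is implemented.

All distribution arithmetic is carried out in log space: at the published
parameters the matrix entries span scales of ``exp(-16 * P)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from multisyn.neuron_core import (
    ActivityProfile,
    ConsistentState,
    FeedbackSpec,
    IOCurve,
    NoRootError,
    SystemPoint,
    consistent_state,
)
from multisyn.rate_rules import RuleDomainError, RuleSpec

__all__ = [
    "StructuralParams",
    "SynapseDistribution",
    "TransitionMatrix",
    "CaseResult",
    "FixedPointDiagram",
    "deletion_prob",
    "pdel_profile",
    "build_transition_matrix",
    "stationary_from_matrix",
    "first_step_distribution",
    "delta_ln_p",
    "pcf_pd_curves",
    "classify_case",
    "continuous_fixed_points",
    "fixed_point_diagram",
    "equilibrium_distribution",
]

Q_DEFAULT = 4.0 / 3.0


@dataclass(frozen=True)
class StructuralParams:
    """Parameters of the stochastic rewiring process.

    Parameters
    ----------
    p_build:
        Per-site, per-step synapse creation probability.
    rho:
        Deletion-scale exponent: the maximum deletion probability (at zero
        weight) is ``p_build**rho``.
    a:
        Weight sensitivity of deletion.
    q:
        Weight exponent in the deletion probability (default 4/3).
    P:
        Number of potential synapses.
    rate_scale:
        Common multiplier on both the creation and the deletion probability.
        It compresses simulated time without changing the equilibrium
        distribution (probabilities are clipped at 1 after scaling); keep it
        at 1 for analytic work.
    """

    p_build: float
    rho: float
    a: float
    P: int
    q: float = Q_DEFAULT
    rate_scale: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.p_build < 1.0):
            raise ValueError("p_build must lie in (0, 1)")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.a < 0:
            raise ValueError("a must be non-negative")
        if self.P < 1 or int(self.P) != self.P:
            raise ValueError("P must be a positive integer")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")

    @classmethod
    def from_log_build(cls, ln_p_build: float, rho: float, a: float, P: int, **kw) -> "StructuralParams":
        return cls(p_build=math.exp(ln_p_build), rho=rho, a=a, P=P, **kw)

    @property
    def p_build_eff(self) -> float:
        """Creation probability after time compression, clipped to (0, 1]."""
        return min(1.0, self.rate_scale * self.p_build)

    def with_(self, **kw) -> "StructuralParams":
        return replace(self, **kw)


def deletion_prob(sp: StructuralParams, w) -> np.ndarray | float:
    """Weight-dependent deletion probability ``p_build**rho * exp(-a^2 w^q)``.

    Monotonically decreasing in the weight; maximal (``p_build**rho``) for a
    weightless synapse.  Scaled by ``sp.rate_scale`` and clipped at 1.
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any(w_arr < 0):
        raise ValueError("weights must be non-negative")
    ln_base = sp.rho * math.log(sp.p_build) + math.log(sp.rate_scale)
    with np.errstate(over="ignore"):
        p = np.exp(ln_base - sp.a**2 * w_arr**sp.q)
    p = np.minimum(p, 1.0)
    return float(p) if np.isscalar(w) or w_arr.ndim == 0 else p


def pdel_profile(sp: StructuralParams, profile: ActivityProfile | Sequence[ConsistentState]) -> np.ndarray:
    """Per-state deletion probabilities from an activity profile.

    Entry ``S`` is the deletion probability of one synapse when ``S``
    synapses are realised.  The entry for ``S = 0`` is never used by the
    chain (there is nothing to delete) and is set to the zero-weight value.
    """
    states = list(profile)
    if len(states) != sp.P + 1:
        raise ValueError(f"profile must contain P+1 = {sp.P + 1} states")
    pdel = np.empty(sp.P + 1)
    for s, st in enumerate(states):
        w = st.w if np.isfinite(st.w) else 0.0
        pdel[s] = deletion_prob(sp, w)
    return pdel


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynapseDistribution:
    """Probability vector over ``S = 0 ... P`` with provenance metadata."""

    p: np.ndarray
    log_p: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if np.any(p < -1e-15):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
        object.__setattr__(self, "p", np.maximum(p, 0.0))
        if self.log_p is None:
            with np.errstate(divide="ignore"):
                object.__setattr__(self, "log_p", np.log(self.p))

    @property
    def P(self) -> int:
        return len(self.p) - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.p))

    def mean(self) -> float:
        return float(np.dot(self.support, self.p))

    def tv_distance(self, other: "SynapseDistribution") -> float:
        n = max(len(self.p), len(other.p))
        a = np.zeros(n)
        b = np.zeros(n)
        a[: len(self.p)] = self.p
        b[: len(other.p)] = other.p
        return 0.5 * float(np.abs(a - b).sum())

    def __len__(self):
        return len(self.p)


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic matrix; entry ``(k, l)`` is P(l -> k synapses)."""

    M: np.ndarray
    pdel_by_S: np.ndarray
    p_build: float

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("M must be square")
        if np.any(M < 0):
            raise ValueError("transition probabilities must be non-negative")
        col = M.sum(axis=0)
        if np.any(np.abs(col - 1.0) > 1e-12):
            raise ValueError("columns must sum to 1 within 1e-12")
        object.__setattr__(self, "M", M)

    @property
    def P(self) -> int:
        return self.M.shape[0] - 1


def _log_binom_pmf(n: int, log_p: np.ndarray, log_1mp: np.ndarray, x: np.ndarray) -> np.ndarray:
    return (
        gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        + x * log_p + (n - x) * log_1mp
    )


def build_transition_matrix(sp: StructuralParams, pdel_by_S: Sequence[float]) -> TransitionMatrix:
    """One-step transition matrix of the synapse-count chain.

    From state ``l``, each of the ``l`` synapses is removed independently
    with probability ``pdel_by_S[l]`` and each of the ``P - l`` sites that
    were vacant at the start of the step gains a synapse independently with
    probability ``p_build`` (sites vacated within the step are not refilled
    until the next one).  The entry ``(k, l)`` convolves the two binomials
    over every split consistent with ``l -> k``; the sums are evaluated in
    log space.
    """
    pdel = np.asarray(pdel_by_S, dtype=float)
    P = sp.P
    if pdel.shape != (P + 1,):
        raise ValueError(f"pdel_by_S must have length P+1 = {P + 1}")
    if np.any(pdel <= 0) or np.any(pdel > 1):
        raise ValueError("deletion probabilities must lie in (0, 1]")
    pb = sp.p_build_eff

    M = np.zeros((P + 1, P + 1))
    log_pb = math.log(pb)
    log_1mpb = math.log1p(-pb) if pb < 1.0 else -np.inf
    for l in range(P + 1):
        pd = pdel[l]
        log_pd = math.log(pd)
        log_1mpd = math.log1p(-pd) if pd < 1.0 else -np.inf
        n_vac = P - l
        # x synapses removed (0..l), b sites built (0..n_vac): k = l - x + b
        x = np.arange(l + 1)
        with np.errstate(invalid="ignore"):
            log_rem = _log_binom_pmf(l, log_pd, log_1mpd, x)
        b = np.arange(n_vac + 1)
        with np.errstate(invalid="ignore"):
            log_bld = _log_binom_pmf(n_vac, log_pb, log_1mpb, b)
        log_rem = np.where(np.isnan(log_rem), -np.inf, log_rem)
        log_bld = np.where(np.isnan(log_bld), -np.inf, log_bld)
        joint = log_rem[:, None] + log_bld[None, :]
        k_of = l - x[:, None] + b[None, :]
        for k in range(P + 1):
            terms = joint[k_of == k]
            if terms.size:
                M[k, l] = math.exp(logsumexp(terms))
    # wash out accumulated rounding so columns are stochastic to 1e-15
    M /= M.sum(axis=0, keepdims=True)
    return TransitionMatrix(M=M, pdel_by_S=pdel, p_build=pb)


def stationary_from_matrix(tm: TransitionMatrix) -> SynapseDistribution:
    """Stationary distribution (eigenvector for eigenvalue 1).

    Solved as the null space of ``M - I`` with an explicit normalization
    row, then polished by power iteration until ``||Mp - p||_inf < 1e-10``.
    """
    M = tm.M
    n = M.shape[0]
    A = M - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    p = np.linalg.solve(A, b)
    p = np.maximum(p, 0.0)
    p /= p.sum()
    for _ in range(10_000):
        residual = float(np.max(np.abs(M @ p - p)))
        if residual < 1e-10:
            break
        p = M @ p
        p /= p.sum()
    else:  # pragma: no cover - defensive
        raise RuntimeError(f"stationary distribution did not converge (residual {residual:.2e})")
    return SynapseDistribution(p=p, meta={"method": "matrix", "residual": residual})


def delta_ln_p(sp: StructuralParams, pdel_by_S: Sequence[float]) -> np.ndarray:
    """Log-probability increments ``ln(p[S]/p[S-1])`` for ``S = 1 ... P``.

    Detailed balance of the one-step (birth-death) approximation gives

        delta[S] = ln p_build + ln((P - S + 1) / S) - ln p_del[S].
    """
    pdel = np.asarray(pdel_by_S, dtype=float)
    P = sp.P
    if pdel.shape != (P + 1,):
        raise ValueError(f"pdel_by_S must have length P+1 = {P + 1}")
    if np.any(pdel[1:] <= 0):
        raise ValueError("deletion probabilities for S >= 1 must be positive")
    S = np.arange(1, P + 1, dtype=float)
    return math.log(sp.p_build_eff) + np.log((P - S + 1) / S) - np.log(pdel[1:])


def first_step_distribution(sp: StructuralParams, pdel_by_S: Sequence[float]) -> SynapseDistribution:
    """Stationary distribution of the birth-death (one-change-per-step) chain.

    Computed by accumulating :func:`delta_ln_p` in log space and
    exp-normalizing once at the end; entries may span hundreds of orders of
    magnitude at realistic parameters.
    """
    delta = delta_ln_p(sp, pdel_by_S)
    log_p = np.concatenate(([0.0], np.cumsum(delta)))
    log_p -= logsumexp(log_p)
    return SynapseDistribution(
        p=np.exp(log_p), log_p=log_p, meta={"method": "first-step"}
    )


# ---------------------------------------------------------------------------
# shape classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseResult:
    """Qualitative shape of the equilibrium distribution (cases 1-6).

    ======  ===========  ==========================================
    case    sign flips   shape
    ======  ===========  ==========================================
    1       0 (+)        one maximum at the upper boundary (P)
    2       0 (-)        one maximum at the lower boundary (0)
    3       1 (+ -)      interior maximum at the sign change
    4       1 (- +)      maxima at both boundaries
    5       2 (+ - +)    maxima at the first sign change and at P
    6       2 (- + -)    maxima at 0 and at the second sign change
    ======  ===========  ==========================================
    """

    case: int
    sign_pattern: str
    zero_crossings: tuple
    maxima: tuple
    degenerate: bool = False


def classify_case(delta: Sequence[float]) -> CaseResult:
    """Classify the increment profile ``delta_ln_p`` into cases 1-6.

    A tie (``delta[S] == 0`` exactly) counts as a crossing at that ``S``;
    the maximum is assigned to the larger-probability neighbour.
    """
    d = np.asarray(delta, dtype=float)
    P = len(d)
    if P < 1:
        raise ValueError("delta must have at least one entry")
    if np.all(d == 0.0):
        return CaseResult(case=0, sign_pattern="0" * P, zero_crossings=(), maxima=(), degenerate=True)

    sign = np.sign(d)
    pattern = "".join("+" if s > 0 else "-" if s < 0 else "0" for s in sign)
    # collapse runs; ties inherit the direction change they sit on
    nz = sign[sign != 0]
    runs = [nz[0]]
    for s in nz[1:]:
        if s != runs[-1]:
            runs.append(s)
    n_flips = len(runs) - 1

    # positions: S where the profile changes sign (last S with the old sign)
    crossings = []
    prev_sign, prev_S = nz[0], None
    signs_with_S = [(int(s), S) for S, s in zip(range(1, P + 1), sign) if s != 0]
    for (s, S) in signs_with_S:
        if prev_S is not None and s != prev_sign:
            crossings.append(S)
        prev_sign, prev_S = s, S

    log_p = np.concatenate(([0.0], np.cumsum(d)))

    def interior_max(S_cross):
        # delta flips + -> - between S_cross-1 and S_cross; the peak is the
        # neighbour with the larger probability
        cand = [S_cross - 1, S_cross]
        cand = [c for c in cand if 0 <= c <= P]
        return int(max(cand, key=lambda c: log_p[c]))

    if n_flips == 0:
        if runs[0] > 0:
            return CaseResult(1, pattern, (), (P,))
        return CaseResult(2, pattern, (), (0,))
    if n_flips == 1:
        if runs[0] > 0:
            return CaseResult(3, pattern, tuple(crossings), (interior_max(crossings[0]),))
        return CaseResult(4, pattern, tuple(crossings), (0, P))
    if n_flips == 2:
        if runs[0] > 0:
            return CaseResult(5, pattern, tuple(crossings), (interior_max(crossings[0]), P))
        return CaseResult(6, pattern, tuple(crossings), (0, interior_max(crossings[1])))
    return CaseResult(
        case=-1, sign_pattern=pattern, zero_crossings=tuple(crossings),
        maxima=(), degenerate=True,
    )


# ---------------------------------------------------------------------------
# p_cf / p_d analysis
# ---------------------------------------------------------------------------


def pcf_pd_curves(sp: StructuralParams, profile: ActivityProfile, rule: RuleSpec,
                  fb: FeedbackSpec | None = None):
    """Combinatorial and deletion log-terms as functions of the postsynaptic rate.

    Returns ``(p_cf, p_d)`` where both are callables of ``v_i*``:

    * ``p_cf(v) = -ln p_build - ln((P - S[v] + 1) / S[v])`` with ``S[v]``
      obtained by monotone interpolation of the activity profile (gamma-
      continued combinatorial factor, continuous in S);
    * ``p_d(v) = -ln p_del(w*(v))`` through the rule's fixed weight.

    Intersections of the two curves sit at the zero crossings of
    :func:`delta_ln_p` evaluated on the discrete states.
    """
    v = profile.v_i
    if np.any(np.diff(v) <= 0):
        raise ValueError("activity profile must be strictly increasing to invert S[v]")
    S_grid = np.arange(len(v), dtype=float)

    def S_of_v(vq):
        vq = np.asarray(vq, dtype=float)
        if np.any(vq < v[0]) or np.any(vq > v[-1]):
            raise ValueError("v_i outside profile range")
        return np.interp(vq, v, S_grid)

    ln_pb = math.log(sp.p_build_eff)

    def p_cf(vq):
        S = np.maximum(S_of_v(vq), 1e-9)
        return -ln_pb - np.log((sp.P - S + 1) / S)

    from multisyn.rate_rules import fixed_weight

    def p_d(vq):
        vq_arr = np.atleast_1d(np.asarray(vq, dtype=float))
        out = np.empty_like(vq_arr)
        for i, vi in enumerate(vq_arr):
            vj = float(fb.presynaptic_rate(vi)) if fb is not None and fb.r1 != 0 else (
                fb.r0 if fb is not None else float("nan")
            )
            out[i] = -math.log(deletion_prob(sp, fixed_weight(rule, vi, vj)))
        return out if np.ndim(vq) else float(out[0])

    return p_cf, p_d


# ---------------------------------------------------------------------------
# continuous fixed points / bifurcation diagram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedPointBranch:
    """Root of the net probability flow at one control value."""

    S: float
    stable: bool
    merged: bool = False  # closer than one discrete state to its neighbour


@dataclass(frozen=True)
class FixedPointDiagram:
    """Continuous-S fixed points swept over a control parameter."""

    control: np.ndarray
    branches: tuple  # tuple of tuples of FixedPointBranch
    varied: str
    failures: tuple = field(default_factory=tuple)

    def n_stable(self) -> np.ndarray:
        return np.array([sum(b.stable for b in bs) for bs in self.branches])

    def bistable_mask(self) -> np.ndarray:
        return self.n_stable() >= 2


def continuous_fixed_points(
    sp: StructuralParams,
    rule: RuleSpec,
    io: IOCurve,
    point: SystemPoint,
    fb: FeedbackSpec | None = None,
    n_scan: int = 600,
) -> tuple:
    """Roots (with stability) of the net flow ``h(S)`` for continuous ``S``.

    ``h(S) = (P - S) p_build - S p_del(w*(S))`` is the expected change of
    the synapse count per step; ``S`` is treated as a real variable and the
    consistent state is re-solved at every scan point.  Roots where ``h``
    changes sign from + to - are stable.  Two fixed points closer together
    than one discrete state are flagged as effectively merged.
    """
    pb = sp.p_build_eff

    def h(S):
        try:
            st = consistent_state(S, point, rule, io, fb)
        except (NoRootError, RuleDomainError):
            return np.nan
        w = st.w if np.isfinite(st.w) else 0.0
        return (sp.P - S) * pb - S * deletion_prob(sp, w)

    Ss = np.linspace(0.0, float(sp.P), n_scan)
    hs = np.array([h(S) for S in Ss])
    valid = np.isfinite(hs)

    roots = []
    for i in range(len(Ss) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        if hs[i] == 0.0:
            roots.append((Ss[i], hs[max(i - 1, 0)] > 0))
            continue
        if hs[i] * hs[i + 1] < 0:
            lo, hi, hlo = Ss[i], Ss[i + 1], hs[i]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                hm = h(mid)
                if not np.isfinite(hm) or hm == 0.0:
                    break
                if (hm > 0) == (hlo > 0):
                    lo, hlo = mid, hm
                else:
                    hi = mid
            roots.append((0.5 * (lo + hi), hs[i] > 0))

    branches = [FixedPointBranch(S=s, stable=st) for s, st in roots]
    # boundary attractors: flow pointing into a boundary
    if valid[-1] and hs[-1] > 0 and not any(abs(b.S - sp.P) < 1e-6 for b in branches):
        branches.append(FixedPointBranch(S=float(sp.P), stable=True))
    if valid[0] and hs[0] < 0 and not any(abs(b.S) < 1e-6 for b in branches):
        branches.insert(0, FixedPointBranch(S=0.0, stable=True))

    branches.sort(key=lambda b: b.S)
    out = []
    for i, b in enumerate(branches):
        near = any(abs(b.S - o.S) < 1.0 for j, o in enumerate(branches) if j != i)
        out.append(FixedPointBranch(S=b.S, stable=b.stable, merged=near))
    return tuple(out)


def fixed_point_diagram(
    sp: StructuralParams,
    rule: RuleSpec,
    io: IOCurve,
    fb: FeedbackSpec | None,
    control_values: Sequence[float],
    varied: str = "post",
    fixed_value: float = None,  # type: ignore[assignment]
    n_scan: int = 400,
) -> FixedPointDiagram:
    """Sweep :func:`continuous_fixed_points` over a stimulation parameter.

    ``varied='post'`` sweeps the baseline rate ``v_i(S=0)`` with
    ``fixed_value`` as the constant ``v_j``; ``varied='pre'`` sweeps ``v_j``
    with ``fixed_value`` as the constant baseline rate.
    """
    if varied not in ("post", "pre"):
        raise ValueError("varied must be 'post' or 'pre'")
    branches, failures = [], []
    for c in control_values:
        if varied == "post":
            pt = SystemPoint(v_j=fixed_value, v_i_S0=min(max(c, 1e-9), 1 - 1e-9))
        else:
            pt = SystemPoint(v_j=c, v_i_S0=fixed_value)
        try:
            branches.append(continuous_fixed_points(sp, rule, io, pt, fb, n_scan=n_scan))
        except (NoRootError, RuleDomainError) as exc:
            branches.append(())
            failures.append((float(c), str(exc)))
    return FixedPointDiagram(
        control=np.asarray(control_values, dtype=float),
        branches=tuple(branches),
        varied=varied,
        failures=tuple(failures),
    )


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------


def equilibrium_distribution(
    sp: StructuralParams,
    rule: RuleSpec,
    io: IOCurve,
    point: SystemPoint,
    fb: FeedbackSpec | None = None,
    method: str = "first-step",
) -> SynapseDistribution:
    """Full pipeline: activity profile -> deletion profile -> distribution."""
    from multisyn.neuron_core import activity_profile

    profile = activity_profile(sp.P, point, rule, io, fb)
    pdel = pdel_profile(sp, profile)
    if method == "first-step":
        dist = first_step_distribution(sp, pdel)
    elif method == "matrix":
        dist = stationary_from_matrix(build_transition_matrix(sp, pdel))
    else:
        raise ValueError("method must be 'first-step' or 'matrix'")
    dist.meta.update(
        {"v_j": point.v_j, "v_i_S0": point.baseline_rate(io), "P": sp.P}
    )
    return dist
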