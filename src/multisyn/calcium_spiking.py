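"""Event-driven integration of the calcium-threshold plasticity rule.

The synaptic weight relaxes with time constant ``tau_w`` towards
potentiation (rate ``gamma_p``) while the calcium trace exceeds ``theta_p``
and towards depression (rate ``gamma_d``) while it exceeds ``theta_d``.
The calcium trace decays exponentially (``tau_c``) and jumps by ``C_pre``
or ``C_post`` at pre-/postsynaptic spikes.  Because the weight equation is
piecewise linear in every interval of constant threshold state, the system
integrates exactly between events -- no time stepping is involved.

The module also provides the ensemble fixed-weight estimator under Poisson
drive and a forward-Euler adaptive exponential integrate-and-fire (AdEx)
f-I curve, both used to build empirical activity/weight maps for the
structural analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "CaRuleParams",
    "SpikeTrain",
    "EmpiricalCurve",
    "AdExParams",
    "ca_integrate",
    "ca_fixed_weight",
    "adex_fi_curve",
    "ca_vw_surface",
    "VWSurface",
    "CORTICAL_PARAMS",
]


@dataclass(frozen=True)
class CaRuleParams:
    """Parameters of the calcium-threshold rule (times in seconds).

    ``tau_c`` is given in seconds here as well; the published cortical value
    22.7 ms is 0.0227.
    """

    tau_w: float = 346.361
    gamma_p: float = 725.085
    gamma_d: float = 331.909
    theta_p: float = 1.3
    theta_d: float = 1.0
    tau_c: float = 0.0227
    C_pre: float = 0.5617
    C_post: float = 1.2396

    def __post_init__(self):
        for name in ("tau_w", "gamma_p", "gamma_d", "theta_p", "theta_d", "tau_c", "C_pre", "C_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.theta_p < self.theta_d:
            raise ValueError("theta_p must be >= theta_d")

    @property
    def w_pot_limit(self) -> float:
        """Stationary weight when both thresholds are permanently exceeded."""
        return self.gamma_p / (self.gamma_p + self.gamma_d)


CORTICAL_PARAMS = CaRuleParams()


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in seconds with a source label ('pre' or 'post')."""

    times: np.ndarray
    source: str = "pre"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("spike times must be non-negative and strictly increasing")
        if self.source not in ("pre", "post"):
            raise ValueError("source must be 'pre' or 'post'")
        object.__setattr__(self, "times", t)

    def __len__(self):
        return len(self.times)

    @classmethod
    def poisson(cls, rate_hz: float, T: float, rng: np.random.Generator, source: str = "pre") -> "SpikeTrain":
        if rate_hz < 0:
            raise ValueError("rate must be non-negative")
        n = rng.poisson(rate_hz * T)
        times = np.sort(rng.uniform(0.0, T, size=n))
        times = times[np.concatenate(([True], np.diff(times) > 0))] if n else times
        return cls(times=times, source=source)


@dataclass(frozen=True)
class EmpiricalCurve:
    """Piecewise-linear sampled curve with strict domain checking."""

    x: np.ndarray
    y: np.ndarray
    name: str = "empirical"

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape or x.size < 2:
            raise ValueError("x and y must be 1-D arrays of equal length >= 2")
        if np.any(np.diff(x) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __call__(self, q):
        q = np.asarray(q, dtype=float)
        if np.any(q < self.x[0] - 1e-12) or np.any(q > self.x[-1] + 1e-12):
            raise ValueError(f"query outside curve domain [{self.x[0]}, {self.x[-1]}]")
        return np.interp(q, self.x, self.y)

    @property
    def domain(self):
        return float(self.x[0]), float(self.x[-1])


# ---------------------------------------------------------------------------
# exact event-driven integration
# ---------------------------------------------------------------------------


@njit(cache=True)
def _segment_update(w, c0, dt, tau_c, tau_w, gp, gd, tp, td):
    """Advance the weight across an inter-event interval of length dt.

    The calcium trace decays from c0; the interval splits at the downward
    crossings of theta_p and theta_d into at most three windows of constant
    threshold state, in each of which the weight ODE is linear and solved
    exactly.
    """
    t_p = 0.0
    if c0 > tp:
        t_p = tau_c * math.log(c0 / tp)
        if t_p > dt:
            t_p = dt
    t_d = 0.0
    if c0 > td:
        t_d = tau_c * math.log(c0 / td)
        if t_d > dt:
            t_d = dt
    # window 1: both thresholds exceeded
    if t_p > 0.0:
        k = (gp + gd) / tau_w
        winf = gp / (gp + gd)
        w = winf + (w - winf) * math.exp(-k * t_p)
    # window 2: only depression threshold exceeded
    if t_d > t_p:
        k = gd / tau_w
        w = w * math.exp(-k * (t_d - t_p))
    # window 3: below both thresholds -- weight frozen
    c = c0 * math.exp(-dt / tau_c)
    if w < 0.0:
        w = 0.0
    elif w > 1.0:
        w = 1.0
    return w, c


@njit(cache=True)
def _ca_run(times, jumps, w0, c0, T, tau_c, tau_w, gp, gd, tp, td):
    """Exact integration over merged event times; returns (w(T), c(T))."""
    w = w0
    c = c0
    t_prev = 0.0
    for i in range(times.shape[0]):
        dt = times[i] - t_prev
        if dt > 0.0:
            w, c = _segment_update(w, c, dt, tau_c, tau_w, gp, gd, tp, td)
        c += jumps[i]
        t_prev = times[i]
    if T > t_prev:
        w, c = _segment_update(w, c, T - t_prev, tau_c, tau_w, gp, gd, tp, td)
    return w, c


def _merge_trains(pre: SpikeTrain, post: SpikeTrain, params: CaRuleParams):
    times = np.concatenate([pre.times, post.times])
    jumps = np.concatenate([
        np.full(len(pre), params.C_pre),
        np.full(len(post), params.C_post),
    ])
    order = np.argsort(times, kind="stable")
    return times[order], jumps[order]


def ca_integrate(
    params: CaRuleParams,
    pre: SpikeTrain,
    post: SpikeTrain,
    w0: float,
    T: float,
    c0: float = 0.0,
    record: bool = False,
):
    """Integrate the calcium rule exactly from 0 to ``T``.

    Returns ``(w_T, c_T)`` or, with ``record=True``, additionally the
    calcium/weight values immediately after every spike event as a
    ``(times, c, w)`` triple.

    Coincident pre/post spikes simply add both calcium jumps (the jumps
    commute).  Exact up to floating point; no time stepping.
    """
    if not (0.0 <= w0 <= 1.0):
        raise ValueError("w0 must lie in [0, 1]")
    if len(pre.times) and pre.times[-1] > T or len(post.times) and post.times[-1] > T:
        raise ValueError("spike trains must lie within [0, T]")
    times, jumps = _merge_trains(pre, post, params)
    p = params
    if not record:
        w, c = _ca_run(times, jumps, float(w0), float(c0), float(T),
                       p.tau_c, p.tau_w, p.gamma_p, p.gamma_d, p.theta_p, p.theta_d)
        return w, c
    w, c = float(w0), float(c0)
    t_prev = 0.0
    rec_t, rec_c, rec_w = [0.0], [c], [w]
    for t, j in zip(times, jumps):
        if t > t_prev:
            w, c = _segment_update(w, c, t - t_prev, p.tau_c, p.tau_w,
                                   p.gamma_p, p.gamma_d, p.theta_p, p.theta_d)
        c += j
        t_prev = t
        rec_t.append(t)
        rec_c.append(c)
        rec_w.append(w)
    if T > t_prev:
        w, c = _segment_update(w, c, T - t_prev, p.tau_c, p.tau_w,
                               p.gamma_p, p.gamma_d, p.theta_p, p.theta_d)
    rec_t.append(T)
    rec_c.append(c)
    rec_w.append(w)
    return w, c, (np.array(rec_t), np.array(rec_c), np.array(rec_w))


# ---------------------------------------------------------------------------
# ensemble fixed weight under Poisson drive
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ensemble_block(ws, cs, rate_pre, rate_post, T_block, seed,
                    tau_c, tau_w, gp, gd, tp, td, Cpre, Cpost):
    """Advance every connection by one block of Poisson stimulation."""
    np.random.seed(seed)
    n = ws.shape[0]
    for i in range(n):
        w = ws[i]
        c = cs[i]
        t = 0.0
        t_pre = np.random.exponential(1.0 / rate_pre)
        t_post = np.random.exponential(1.0 / rate_post)
        while True:
            t_next = t_pre if t_pre < t_post else t_post
            if t_next >= T_block:
                w, c = _segment_update(w, c, T_block - t, tau_c, tau_w, gp, gd, tp, td)
                break
            w, c = _segment_update(w, c, t_next - t, tau_c, tau_w, gp, gd, tp, td)
            if t_pre < t_post:
                c += Cpre
                t_pre += np.random.exponential(1.0 / rate_pre)
            else:
                c += Cpost
                t_post += np.random.exponential(1.0 / rate_post)
            t = t_next
        ws[i] = w
        cs[i] = c


@dataclass(frozen=True)
class FixedWeightResult:
    mean: float
    sd: float
    n_blocks: int
    converged: bool
    history: np.ndarray = field(default_factory=lambda: np.empty(0))


def ca_fixed_weight(
    params: CaRuleParams,
    rate_pre: float,
    rate_post: float,
    n_ensemble: int = 500,
    block_spikes: int = 200,
    tol: float = 0.005,
    seed: int = 0,
    w0: float = 0.5,
    max_blocks: int = 400,
) -> FixedWeightResult:
    """Ensemble estimate of the stationary weight under Poisson stimulation.

    ``n_ensemble`` independent connections are driven by independent pre/post
    Poisson trains; at block boundaries (each block covers at least
    ``block_spikes`` expected spikes from each site) the ensemble mean and
    standard deviation are evaluated, and the run stops once the mean has
    changed by less than ``tol`` for three consecutive blocks.
    """
    if rate_pre <= 0 or rate_post <= 0:
        raise ValueError("rates must be positive")
    if block_spikes < 1:
        raise ValueError("block_spikes must be >= 1")
    p = params
    T_block = block_spikes / min(rate_pre, rate_post)
    ws = np.full(n_ensemble, float(w0))
    cs = np.zeros(n_ensemble)
    means = []
    quiet = 0
    prev_mean = float(np.mean(ws))
    for block in range(1, max_blocks + 1):
        _ensemble_block(ws, cs, rate_pre, rate_post, T_block, seed + block,
                        p.tau_c, p.tau_w, p.gamma_p, p.gamma_d,
                        p.theta_p, p.theta_d, p.C_pre, p.C_post)
        mean = float(np.mean(ws))
        means.append(mean)
        quiet = quiet + 1 if abs(mean - prev_mean) < tol else 0
        prev_mean = mean
        if quiet >= 3:
            return FixedWeightResult(mean=mean, sd=float(np.std(ws)),
                                     n_blocks=block, converged=True,
                                     history=np.array(means))
    return FixedWeightResult(mean=prev_mean, sd=float(np.std(ws)),
                             n_blocks=max_blocks, converged=False,
                             history=np.array(means))


# ---------------------------------------------------------------------------
# AdEx f-I curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdExParams:
    """Adaptive exponential integrate-and-fire parameters.

    Units: capacitance pF, conductances nS, voltages mV, currents pA,
    times ms.  The default set is the published tonic-firing configuration
    of the model family; it is configuration, not a fitted value.
    """

    C: float = 281.0
    g_L: float = 30.0
    E_L: float = -70.6
    V_T: float = -50.4
    Delta_T: float = 2.0
    tau_w: float = 144.0
    a: float = 4.0
    b: float = 80.5
    V_reset: float = -70.6
    V_peak: float = 0.0


@njit(cache=True)
def _adex_run(I0, noise_frac, duration_ms, dt_ms, seed,
              C, gL, EL, VT, DT, tauw, a, b, Vreset, Vpeak):
    np.random.seed(seed)
    V = EL
    w = 0.0
    n_steps = int(duration_ms / dt_ms)
    n_spikes = 0
    for _ in range(n_steps):
        I = I0
        if noise_frac > 0.0:
            I += noise_frac * I0 * np.random.normal()
        exp_arg = (V - VT) / DT
        if exp_arg > 30.0:
            exp_arg = 30.0
        dV = (-gL * (V - EL) + gL * DT * math.exp(exp_arg) - w + I) / C
        dw = (a * (V - EL) - w) / tauw
        V += dt_ms * dV
        w += dt_ms * dw
        if not math.isfinite(V):
            return -1.0
        if V >= Vpeak:
            V = Vreset
            w += b
            n_spikes += 1
    return n_spikes / (duration_ms / 1000.0)


def adex_fi_curve(
    adex: AdExParams,
    I_min: float,
    I_max: float,
    I_step: float = 0.5,
    duration: float = 10.0,
    dt: float = 5e-5,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> EmpiricalCurve:
    """Mean firing rate (Hz) versus injected current (pA), forward Euler.

    ``duration`` and ``dt`` are in seconds; the published protocol used
    2500 s per current and 0.5 pA steps, which is far beyond desk scale --
    shorten the duration for exploratory use.
    """
    if I_min >= I_max:
        raise ValueError("I_min must be < I_max")
    if dt > 5e-5 + 1e-15:
        raise ValueError("dt must be <= 0.05 ms for Euler stability")
    currents = np.arange(I_min, I_max + I_step / 2, I_step)
    rates = np.empty_like(currents)
    p = adex
    for i, I0 in enumerate(currents):
        r = _adex_run(I0, noise_frac, duration * 1e3, dt * 1e3, seed + i,
                      p.C, p.g_L, p.E_L, p.V_T, p.Delta_T, p.tau_w,
                      p.a, p.b, p.V_reset, p.V_peak)
        if r < 0:
            raise FloatingPointError(f"AdEx integration diverged at I = {I0} pA")
        rates[i] = r
    return EmpiricalCurve(x=currents, y=rates, name="adex-fi")


# ---------------------------------------------------------------------------
# fixed-weight surface over rate grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VWSurface:
    """Fixed weight on a (pre-rate, post-rate) grid with bilinear interpolation."""

    rates_pre: np.ndarray
    rates_post: np.ndarray
    weights: np.ndarray  # shape (len(rates_pre), len(rates_post))
    w_scale: float = 1.0

    def __call__(self, rate_pre, rate_post):
        rp = float(rate_pre)
        rq = float(rate_post)
        xs, ys = self.rates_pre, self.rates_post
        if not (xs[0] <= rp <= xs[-1] and ys[0] <= rq <= ys[-1]):
            raise ValueError("query outside simulated rate grid")
        i = min(np.searchsorted(xs, rp, side="right") - 1, len(xs) - 2)
        j = min(np.searchsorted(ys, rq, side="right") - 1, len(ys) - 2)
        tx = 0.0 if xs[i + 1] == xs[i] else (rp - xs[i]) / (xs[i + 1] - xs[i])
        ty = 0.0 if ys[j + 1] == ys[j] else (rq - ys[j]) / (ys[j + 1] - ys[j])
        z = (
            self.weights[i, j] * (1 - tx) * (1 - ty)
            + self.weights[i + 1, j] * tx * (1 - ty)
            + self.weights[i, j + 1] * (1 - tx) * ty
            + self.weights[i + 1, j + 1] * tx * ty
        )
        return self.w_scale * z

    def curve_at_pre(self, rate_pre: float) -> EmpiricalCurve:
        y = np.array([self(rate_pre, rq) for rq in self.rates_post])
        return EmpiricalCurve(x=self.rates_post.copy(), y=y, name=f"vw@pre={rate_pre}")


def ca_vw_surface(
    params: CaRuleParams,
    rates_pre,
    rates_post,
    w_scale: float = 1.0,
    n_ensemble: int = 500,
    tol: float = 0.005,
    seed: int = 0,
    **kw,
) -> VWSurface:
    """Simulate :func:`ca_fixed_weight` on a rate grid and wrap it for lookup.

    ``w_scale`` converts the dimensionless stationary weight into the units
    used downstream (the published conversion is 0.035 nA/Hz; whether it
    multiplies the weight or the per-rate current is notation-ambiguous in
    the source, so it is exposed as a single named factor).
    """
    rates_pre = np.asarray(rates_pre, dtype=float)
    rates_post = np.asarray(rates_post, dtype=float)
    W = np.empty((len(rates_pre), len(rates_post)))
    for i, rp in enumerate(rates_pre):
        for j, rq in enumerate(rates_post):
            res = ca_fixed_weight(params, rp, rq, n_ensemble=n_ensemble,
                                  tol=tol, seed=seed + 1000 * i + j, **kw)
            W[i, j] = res.mean
    return VWSurface(rates_pre=rates_pre, rates_post=rates_post, weights=W, w_scale=w_scale)
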