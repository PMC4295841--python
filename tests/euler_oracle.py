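"""Brute-force Euler reference integrators used as oracles in tests.

Deliberately independent of the event-driven implementations: fixed-step
forward Euler with spike jumps applied at their time bins.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def euler_calcium(times, jumps, w0, c0, T, dt, tau_c, tau_w, gp, gd, tp, td):
    """Forward-Euler calcium-rule integration with step dt."""
    n_steps = int(round(T / dt))
    w = w0
    c = c0
    k = 0
    n_events = times.shape[0]
    for step in range(n_steps):
        t = step * dt
        while k < n_events and times[k] < t + dt:
            c += jumps[k]
            k += 1
        dw = 0.0
        if c > tp:
            dw += gp * (1.0 - w)
        if c > td:
            dw -= gd * w
        w += dt * dw / tau_w
        c -= dt * c / tau_c
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
    return w


@njit(cache=True)
def euler_adex(I0, duration_ms, dt_ms, C, gL, EL, VT, DT, tauw, a, b, Vreset, Vpeak):
    """Deterministic AdEx forward Euler; returns the spike count."""
    V = EL
    w = 0.0
    n_steps = int(duration_ms / dt_ms)
    n_spikes = 0
    for _ in range(n_steps):
        exp_arg = (V - VT) / DT
        if exp_arg > 30.0:
            exp_arg = 30.0
        dV = (-gL * (V - EL) + gL * DT * math.exp(exp_arg) - w + I0) / C
        dw = (a * (V - EL) - w) / tauw
        V += dt_ms * dV
        w += dt_ms * dw
        if V >= Vpeak:
            V = Vreset
            w += b
            n_spikes += 1
    return n_spikes
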