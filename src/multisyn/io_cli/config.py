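"""Declarative YAML configuration shared by all CLI subcommands.

A config file has up to six sections; unknown keys are rejected early so
typos fail loudly::

    structural: {ln_p_build: -16.0, rho: 0.125, a: 2.0, P: 12}
    rule:       {kind: bcm_scaling, mu: 0.2, theta: 0.08, kappa: 9.0, v_tss: 0.1}
    neuron:     {io: logistic, feedback: {r0: 0.0, r1: 0.0}}
    point:      {v_j: 0.656, v_i_S0: 0.2975}
    protocol:   {varied: post, step: 0.01, lower: 0.05, upper: 1.0, dwell: 10000, n_cycles: 20}
    rng:        {seed: 0}

``structural`` accepts either ``p_build`` or ``ln_p_build``.  The neuron
section's ``io`` is ``logistic`` or ``empirical:<tsv-file>``.
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from multisyn.markov_structural import StructuralParams
from multisyn.neuron_core import FeedbackSpec, IOCurve, SystemPoint
from multisyn.rate_rules import RuleSpec
from multisyn.stochastic_simulator import HysteresisProtocol

__all__ = ["load_config", "build_components"]

_SECTIONS = {"structural", "rule", "neuron", "point", "protocol", "rng", "grid"}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    return cfg


def _structural(section: dict) -> StructuralParams:
    sec = dict(section)
    if "ln_p_build" in sec:
        sec["p_build"] = math.exp(sec.pop("ln_p_build"))
    return StructuralParams(**sec)


def _rule(section: dict) -> RuleSpec:
    return RuleSpec(**section)


def _neuron(section: dict):
    sec = dict(section or {})
    io_spec = sec.get("io", "logistic")
    if io_spec == "logistic":
        io = IOCurve.logistic()
    elif isinstance(io_spec, str) and io_spec.startswith("empirical:"):
        from multisyn.io_cli.formats import read_curve

        curve = read_curve(io_spec.split(":", 1)[1])
        io = IOCurve.from_samples(curve.x, curve.y, name="empirical")
    else:
        raise ValueError(f"unknown io curve spec {io_spec!r}")
    fb_sec = sec.get("feedback")
    fb = FeedbackSpec(**fb_sec) if fb_sec else None
    return io, fb


def _point(section: dict) -> SystemPoint:
    return SystemPoint(**section)


def build_components(cfg: dict) -> dict:
    """Instantiate model objects from a parsed config mapping.

    Returns a dict with keys among ``structural``, ``rule``, ``io``, ``fb``,
    ``point``, ``protocol``, ``seed`` -- only those whose sections exist.
    """
    out = {}
    if "structural" in cfg:
        out["structural"] = _structural(cfg["structural"])
    if "rule" in cfg:
        out["rule"] = _rule(cfg["rule"])
    if "neuron" in cfg or True:
        io, fb = _neuron(cfg.get("neuron", {}))
        out["io"] = io
        out["fb"] = fb
    if "point" in cfg:
        out["point"] = _point(cfg["point"])
    if "protocol" in cfg:
        out["protocol"] = HysteresisProtocol(**cfg["protocol"])
    out["seed"] = int(cfg.get("rng", {}).get("seed", 0))
    out["grid"] = cfg.get("grid", {})
    return out
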