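"""Plain-text tabular formats.

Everything is TSV with '#'-prefixed comment/metadata lines.  Metadata keys
are written as ``# key = value`` and returned verbatim on reading, so a
write-read round trip is lossless up to float formatting (12 significant
digits).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from multisyn.calcium_spiking import EmpiricalCurve, SpikeTrain
from multisyn.fit_stats import ExperimentData
from multisyn.markov_structural import SynapseDistribution
from multisyn.stochastic_simulator import HysteresisTrace

__all__ = [
    "MalformedFileError",
    "provenance_lines",
    "write_distribution", "read_distribution",
    "write_experiment", "read_experiment",
    "write_hysteresis", "read_hysteresis",
    "write_curve", "read_curve",
    "write_spike_train", "read_spike_train",
]

_FLOAT_FMT = "{:.12g}"


class MalformedFileError(ValueError):
    """Raised with the offending line number on parse failure."""


def provenance_lines(config: dict = None, seed: int = None) -> list[str]:
    """Comment block identifying the run (config hash, seed, version)."""
    from multisyn import __version__

    lines = [f"# multisyn_version = {__version__}"]
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_sha256 = {digest}")
    if seed is not None:
        lines.append(f"# seed = {seed}")
    return lines


def _write_table(path, columns, header, meta: dict = None, extra_comments=()):
    path = Path(path)
    lines = list(extra_comments)
    for k, v in (meta or {}).items():
        lines.append(f"# {k} = {v}")
    lines.append("# " + "\t".join(header))
    for row in zip(*columns):
        lines.append("\t".join(_FLOAT_FMT.format(v) if isinstance(v, float) else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _read_table(path, n_cols):
    path = Path(path)
    meta = {}
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != n_cols:
            raise MalformedFileError(f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise MalformedFileError(f"{path}:{lineno}: {exc}") from exc
    return meta, np.array(rows) if rows else np.empty((0, n_cols))


# -- SynapseDistribution -----------------------------------------------------


def write_distribution(path, dist: SynapseDistribution, extra_comments=()):
    meta = {k: v for k, v in dist.meta.items() if np.isscalar(v) or isinstance(v, str)}
    _write_table(path, (dist.support.tolist(), [float(p) for p in dist.p]),
                 header=("S", "p"), meta=meta, extra_comments=extra_comments)


def read_distribution(path, strict: bool = False) -> SynapseDistribution:
    meta, rows = _read_table(path, 2)
    if rows.size == 0:
        raise MalformedFileError(f"{path}: empty distribution")
    S = rows[:, 0].astype(int)
    if not np.array_equal(S, np.arange(len(S))):
        raise MalformedFileError(f"{path}: support must be contiguous from 0")
    p = rows[:, 1]
    if np.any(p < 0):
        raise MalformedFileError(f"{path}: negative probabilities")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        if strict:
            raise MalformedFileError(f"{path}: probabilities sum to {total!r} (strict mode)")
        import warnings

        warnings.warn(f"{path}: probabilities sum to {total:.6g}; renormalizing")
        p = p / total
    return SynapseDistribution(p=p, meta=dict(meta))


# -- ExperimentData ----------------------------------------------------------


def write_experiment(path, exp: ExperimentData, extra_comments=()):
    meta = {"n_exp": exp.n_exp}
    if exp.label:
        meta["label"] = exp.label
    _write_table(path, (list(range(len(exp.freqs))), [float(f) for f in exp.freqs]),
                 header=("S", "frequency"), meta=meta, extra_comments=extra_comments)


def read_experiment(path, strict: bool = False) -> ExperimentData:
    meta, rows = _read_table(path, 2)
    if rows.size == 0:
        raise MalformedFileError(f"{path}: empty experiment file")
    if "n_exp" not in meta:
        raise MalformedFileError(f"{path}: missing '# n_exp = <int>' header")
    f = rows[:, 1]
    if np.any(f < 0):
        raise MalformedFileError(f"{path}: negative frequencies")
    total = f.sum()
    if abs(total - 1.0) > 1e-9:
        if strict and abs(total - round(total)) > 1e-9:
            raise MalformedFileError(f"{path}: frequencies sum to {total!r} (strict mode)")
        f = f / total
    return ExperimentData(freqs=f, n_exp=int(float(meta["n_exp"])), label=meta.get("label", ""))


# -- HysteresisTrace ---------------------------------------------------------


def write_hysteresis(path, trace: HysteresisTrace, extra_comments=()):
    meta = {"varied": trace.varied, "n_cycles": trace.per_cycle_up.shape[0]}
    _write_table(
        path,
        ([float(x) for x in trace.levels],
         [float(x) for x in trace.mean_up],
         [float(x) for x in trace.mean_down]),
        header=("level", "mean_up", "mean_down"),
        meta=meta, extra_comments=extra_comments,
    )


def read_hysteresis(path) -> HysteresisTrace:
    meta, rows = _read_table(path, 3)
    n_cycles = int(float(meta.get("n_cycles", 1)))
    return HysteresisTrace(
        levels=rows[:, 0], mean_up=rows[:, 1], mean_down=rows[:, 2],
        per_cycle_up=np.tile(rows[:, 1], (n_cycles, 1)),
        per_cycle_down=np.tile(rows[:, 2], (n_cycles, 1)),
        varied=meta.get("varied", "post"),
    )


# -- EmpiricalCurve ----------------------------------------------------------


def write_curve(path, curve: EmpiricalCurve, extra_comments=()):
    _write_table(path, ([float(x) for x in curve.x], [float(y) for y in curve.y]),
                 header=("x", "y"), meta={"name": curve.name}, extra_comments=extra_comments)


def read_curve(path) -> EmpiricalCurve:
    meta, rows = _read_table(path, 2)
    if len(rows) < 2:
        raise MalformedFileError(f"{path}: a curve needs at least two samples")
    return EmpiricalCurve(x=rows[:, 0], y=rows[:, 1], name=meta.get("name", "empirical"))


# -- SpikeTrain --------------------------------------------------------------


def write_spike_train(path, train: SpikeTrain, extra_comments=()):
    _write_table(path, ([float(t) for t in train.times], [train.source] * len(train)),
                 header=("time_s", "source"), extra_comments=extra_comments)


def read_spike_train(path) -> SpikeTrain:
    path = Path(path)
    times, source = [], None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MalformedFileError(f"{path}:{lineno}: expected 'time source'")
        try:
            t = float(parts[0])
        except ValueError as exc:
            raise MalformedFileError(f"{path}:{lineno}: {exc}") from exc
        if times and t <= times[-1]:
            raise MalformedFileError(f"{path}:{lineno}: spike times must strictly increase")
        if source is None:
            source = parts[1]
        elif parts[1] != source:
            raise MalformedFileError(f"{path}:{lineno}: mixed source labels in one file")
        times.append(t)
    return SpikeTrain(times=np.array(times), source=source or "pre")
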