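"""Monte-Carlo goodness-of-fit and activity confidence regions.

The experimental synapse-count histograms are too sparse for standard
tests, so model and data are compared by resampling: ``N_exp`` connections
are drawn from the model distribution, the squared error between the
resampled histogram and the model is recorded ``N_MC`` times, and the
p-value is the probability of a squared error at least as large as the
experimental one.  Scanning the p-value over a grid of activity pairs
``(v_j, v_i(S=0))`` yields the confidence region of activities at which the
model can account for the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from multisyn.markov_structural import (
    StructuralParams,
    SynapseDistribution,
    first_step_distribution,
    pdel_profile,
)
from multisyn.neuron_core import (
    FeedbackSpec,
    IOCurve,
    NoRootError,
    SystemPoint,
    activity_profile,
)
from multisyn.rate_rules import RuleDomainError, RuleSpec

__all__ = [
    "ExperimentData",
    "MCConfig",
    "ConfidenceRegion",
    "PPrior",
    "squared_error",
    "mc_pvalue",
    "scan_confidence_region",
    "mixture_over_P",
    "cline_and_expectation",
    "default_potential_prior",
]


@dataclass(frozen=True)
class ExperimentData:
    """Sparse synapse-count histogram with its sample size.

    ``freqs`` are relative frequencies over ``S = 0 ... len-1`` and must sum
    to one; ``n_exp`` is the number of sampled neuron pairs (sometimes only
    known indirectly, by dividing the number of connected pairs by the
    connection probability).
    """

    freqs: np.ndarray
    n_exp: int
    label: str = ""
    connection_probability: float = None  # type: ignore[assignment]

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1 (normalize counts first)")
        if self.n_exp < 1:
            raise ValueError("n_exp must be >= 1")
        object.__setattr__(self, "freqs", f)

    @classmethod
    def from_counts(cls, counts: Sequence[float], label: str = "", n_exp: int = None) -> "ExperimentData":
        c = np.asarray(counts, dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValueError("counts must contain positive mass")
        return cls(freqs=c / total, n_exp=int(n_exp if n_exp is not None else round(total)), label=label)


@dataclass(frozen=True)
class MCConfig:
    """Monte-Carlo resampling configuration."""

    n_mc: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_mc < 100:
            raise ValueError("n_mc must be >= 100")


def _pad_pair(a: np.ndarray, b: np.ndarray):
    n = max(len(a), len(b))
    pa = np.zeros(n)
    pb = np.zeros(n)
    pa[: len(a)] = a
    pb[: len(b)] = b
    return pa, pb


def squared_error(p_model, p_sample) -> float:
    """Sum of squared per-``S`` differences; shorter support is zero-padded."""
    a = np.asarray(getattr(p_model, "p", p_model), dtype=float)
    b = np.asarray(getattr(p_sample, "p", p_sample), dtype=float)
    pa, pb = _pad_pair(a, b)
    return float(np.sum((pa - pb) ** 2))


@dataclass(frozen=True)
class PValueResult:
    p_greater: float       # strictly larger resampled errors (published rule)
    p_greater_equal: float  # conservative tie handling
    se_exp: float

    @property
    def p(self) -> float:
        return self.p_greater_equal

    def __float__(self):
        return self.p

    def __gt__(self, other):
        return self.p > float(other)

    def __lt__(self, other):
        return self.p < float(other)


def mc_pvalue(p_model, experiment: ExperimentData, cfg: MCConfig,
              rng: np.random.Generator = None) -> PValueResult:
    """Probability that model resampling yields a larger error than the data.

    Draws ``n_mc`` histograms of ``n_exp`` samples from the model
    distribution and compares their squared errors with the experimental
    one.  Both the strict count (published definition) and the
    larger-or-equal count (conservative under ties) are reported; the
    conservative value is used as the primary ``p``.
    """
    model = np.asarray(getattr(p_model, "p", p_model), dtype=float)
    pm, pe = _pad_pair(model, experiment.freqs)
    se_exp = float(np.sum((pm - pe) ** 2))
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    counts = rng.multinomial(experiment.n_exp, pm, size=cfg.n_mc)
    se_rand = np.sum((counts / experiment.n_exp - pm) ** 2, axis=1)
    n_gt = int(np.sum(se_rand > se_exp))
    n_ge = int(np.sum(se_rand >= se_exp))
    return PValueResult(
        p_greater=n_gt / cfg.n_mc,
        p_greater_equal=n_ge / cfg.n_mc,
        se_exp=se_exp,
    )


# ---------------------------------------------------------------------------
# confidence regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfidenceRegion:
    """p-values on an activity grid plus the derived 95% region summaries.

    ``pvals[i, j]`` corresponds to ``v_j_grid[i]`` and ``v_post_grid[j]``
    (baseline rate ``v_i(S=0)``); cells where the model could not be
    evaluated carry NaN and are excluded from the summaries.
    """

    v_j_grid: np.ndarray
    v_post_grid: np.ndarray
    pvals: np.ndarray
    e_vi: np.ndarray = None  # type: ignore[assignment]  # expected postsynaptic rate per cell
    threshold: float = 0.05
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.pvals > self.threshold

    @property
    def coverage(self) -> float:
        return float(np.isfinite(self.pvals).mean())

    @property
    def area(self) -> float:
        """Fraction of the (evaluable) grid inside the region."""
        return float(self.mask.mean())

    @property
    def mean_pre(self) -> float:
        m = self.mask
        if not m.any():
            return float("nan")
        vj = np.broadcast_to(self.v_j_grid[:, None], m.shape)
        return float(vj[m].mean())

    @property
    def mean_post(self) -> float:
        m = self.mask
        if not m.any():
            return float("nan")
        vp = np.broadcast_to(self.v_post_grid[None, :], m.shape)
        return float(vp[m].mean())

    def summary(self) -> dict:
        return {
            "area": self.area,
            "mean_pre": self.mean_pre,
            "mean_post": self.mean_post,
            "coverage": self.coverage,
            "threshold": self.threshold,
        }


def scan_confidence_region(
    v_j_grid,
    v_post_grid,
    sp: StructuralParams,
    rule: RuleSpec,
    io: IOCurve,
    experiment: ExperimentData,
    cfg: MCConfig,
    fb: FeedbackSpec | None = None,
    threshold: float = 0.05,
    compute_expectation: bool = True,
) -> ConfidenceRegion:
    """Monte-Carlo p-value per grid cell of ``(v_j, v_i(S=0))``.

    Per-cell random streams are spawned deterministically from the master
    seed, so the scan is reproducible regardless of evaluation order.
    Unsolvable cells (no consistent state for some ``S``) get NaN.
    """
    v_j_grid = np.asarray(v_j_grid, dtype=float)
    v_post_grid = np.asarray(v_post_grid, dtype=float)
    pvals = np.full((len(v_j_grid), len(v_post_grid)), np.nan)
    e_vi = np.full_like(pvals, np.nan)
    children = np.random.SeedSequence(cfg.seed).spawn(pvals.size)
    for i, vj in enumerate(v_j_grid):
        for j, vpost in enumerate(v_post_grid):
            rng = np.random.default_rng(children[i * len(v_post_grid) + j])
            try:
                pt = SystemPoint(v_j=vj, v_i_S0=vpost)
                prof = activity_profile(sp.P, pt, rule, io, fb)
                dist = first_step_distribution(sp, pdel_profile(sp, prof))
            except (NoRootError, RuleDomainError, ValueError):
                continue
            pvals[i, j] = mc_pvalue(dist, experiment, cfg, rng=rng).p
            if compute_expectation:
                e_vi[i, j] = float(np.dot(dist.p, prof.v_i))
    return ConfidenceRegion(
        v_j_grid=v_j_grid,
        v_post_grid=v_post_grid,
        pvals=pvals,
        e_vi=e_vi,
        threshold=threshold,
        meta={"n_mc": cfg.n_mc, "seed": cfg.seed, "n_exp": experiment.n_exp,
              "experiment": experiment.label},
    )


# ---------------------------------------------------------------------------
# mixture over the number of potential synapses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PPrior:
    """Probability distribution over the number of potential synapses.

    ``probs[k]`` is the probability of ``P = P_values[k]``.
    """

    P_values: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P_values, dtype=int)
        q = np.asarray(self.probs, dtype=float)
        if P.shape != q.shape:
            raise ValueError("P_values and probs must have equal shape")
        if np.any(P < 1):
            raise ValueError("potential synapse counts must be >= 1")
        if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be non-negative and sum to 1")
        object.__setattr__(self, "P_values", P)
        object.__setattr__(self, "probs", q)


def default_potential_prior(P_max: int = 20) -> PPrior:
    """Illustrative prior over P in [1, P_max], peaked below P = 12.

    The published analysis consumed an externally estimated distribution
    whose numbers are not reprinted; this stand-in (a discretized gamma
    bump) is a labelled fixture, not ground truth.
    """
    P = np.arange(1, P_max + 1)
    shape, scale = 5.0, 2.0
    q = P ** (shape - 1) * np.exp(-P / scale)
    q = q / q.sum()
    return PPrior(P_values=P, probs=q)


def mixture_over_P(prior: PPrior, per_P: dict) -> SynapseDistribution:
    """Prior-weighted mixture of per-``P`` distributions, zero-padded.

    ``per_P`` maps each ``P`` with prior mass to its
    :class:`SynapseDistribution` (support ``0 ... P``).
    """
    missing = [int(P) for P, q in zip(prior.P_values, prior.probs) if q > 0 and int(P) not in per_P]
    if missing:
        raise KeyError(f"missing component distributions for P = {missing}")
    n = max(len(per_P[int(P)].p) for P, q in zip(prior.P_values, prior.probs) if q > 0)
    mix = np.zeros(n)
    for P, q in zip(prior.P_values, prior.probs):
        if q == 0:
            continue
        comp = per_P[int(P)].p
        mix[: len(comp)] += q * comp
    return SynapseDistribution(p=mix / mix.sum(), meta={"method": "P-mixture"})


# ---------------------------------------------------------------------------
# cline intersections and expected activities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClineIntersections:
    """Grid cells where the region meets the equal-activity clines."""

    baseline_cells: tuple  # (v_j, v_post) pairs with v_i(S=0) = v_j inside the region
    expectation_cells: tuple  # (v_j, v_post, E[v_i]) with E[v_i] = v_j inside the region

    @property
    def empty(self) -> bool:
        return not (self.baseline_cells or self.expectation_cells)


def cline_and_expectation(region: ConfidenceRegion) -> ClineIntersections:
    """Intersect the confidence region with the equal pre/post activity clines.

    Two clines are used: the baseline rate cline ``v_i(S=0) = v_j`` and the
    expected-rate cline ``E[v_i] = v_j`` (with the expectation over the
    stationary distribution, precomputed during the scan).  A cell counts as
    intersected when it lies inside the region and the cline passes within
    half a grid spacing (baseline) or when the sign of ``E[v_i] - v_j``
    changes across neighbouring in-region cells (expectation).
    """
    mask = region.mask
    vj = region.v_j_grid
    vp = region.v_post_grid
    dv = 0.5 * max(
        np.diff(vj).max() if len(vj) > 1 else 0.0,
        np.diff(vp).max() if len(vp) > 1 else 0.0,
    )
    baseline = [
        (float(vj[i]), float(vp[j]))
        for i in range(len(vj))
        for j in range(len(vp))
        if mask[i, j] and abs(vj[i] - vp[j]) <= dv + 1e-15
    ]
    expectation = []
    if region.e_vi is not None:
        g = region.e_vi - vj[:, None]
        for i in range(len(vj)):
            for j in range(len(vp)):
                if not mask[i, j] or not np.isfinite(g[i, j]):
                    continue
                neighbours = [(i + 1, j), (i, j + 1)]
                for (i2, j2) in neighbours:
                    if i2 < len(vj) and j2 < len(vp) and mask[i2, j2] and np.isfinite(g[i2, j2]):
                        if g[i, j] == 0.0 or g[i, j] * g[i2, j2] < 0:
                            expectation.append(
                                (float(vj[i]), float(vp[j]), float(region.e_vi[i, j]))
                            )
                            break
    return ClineIntersections(
        baseline_cells=tuple(baseline), expectation_cells=tuple(expectation)
    )
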