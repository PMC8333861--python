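"""Sensitivity analyses: one-way (tornado), probabilistic, CEAC and EVPI.

One-way analysis re-runs the full deterministic pipeline with one
parameter at its low or high bound.  Because the base case is dominant
(negative incremental cost, positive incremental QALYs) raw ICERs are
sign-unstable, so the default tornado outcome is the incremental net
monetary benefit at the configured willingness-to-pay; ICER output is
available with dominance flags.

Probabilistic analysis samples every parameter that carries a
distribution (gamma for costs, beta for utilities).  Parameters shared
between arms (dialysis and transplant costs, utilities) are drawn once
per iteration and applied to both arms, so no spurious incremental
variance is manufactured.  Transition probabilities carry no published
distributions and stay fixed, which also means the cohort traces can be
computed once and reused across iterations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTrace, expand_matrices, initial_occupancy, run_cohort
from .economics import run_arm, run_base_case
from .parameters import ModelConfig, ValidationError

__all__ = [
    "rng_stream",
    "TornadoEntry",
    "run_owsa",
    "tornado_frame",
    "sample_draws",
    "sample_draw",
    "PsaOutput",
    "run_psa",
    "ceac",
    "ceac_point",
    "evpi",
    "default_wtp_grid",
]


def rng_stream(master_seed: int, name: str) -> np.random.Generator:
    """Independent named random stream derived from one master seed.

    Streams for scenario generation, probabilistic analysis and
    microsimulation are decoupled so that adding iterations to one stage
    never perturbs another.
    """
    return np.random.default_rng(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
    )


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    low: float
    high: float
    outcome_at_low: float
    outcome_at_high: float
    spread: float
    flag_low: str = ""
    flag_high: str = ""


def _deterministic_outcome(config: ModelConfig, overrides: Mapping[str, float],
                           outcome: str) -> tuple[float, str]:
    res = run_base_case(config, overrides)
    if outcome == "inmb":
        return res.inmb, res.dominance
    if outcome == "icer":
        return res.icer, res.dominance
    raise ValidationError(f"unknown tornado outcome {outcome!r}")


def run_owsa(config: ModelConfig, outcome: str = "inmb") -> list[TornadoEntry]:
    """Vary each ranged parameter to its bounds, all else at base.

    Returns entries sorted by spread (descending); spread is the
    absolute difference between the outcome at the high and low bound.
    """
    entries = []
    for pid, p in config.parameters.items():
        if p.owsa is None:
            continue
        at_low, flag_low = _deterministic_outcome(config, {pid: p.owsa.low}, outcome)
        at_high, flag_high = _deterministic_outcome(config, {pid: p.owsa.high}, outcome)
        spread = abs(at_high - at_low)
        entries.append(TornadoEntry(
            parameter_id=pid, low=p.owsa.low, high=p.owsa.high,
            outcome_at_low=at_low, outcome_at_high=at_high,
            spread=spread if np.isfinite(spread) else np.nan,
            flag_low=flag_low, flag_high=flag_high,
        ))
    entries.sort(key=lambda e: (-(e.spread if np.isfinite(e.spread) else np.inf),
                                e.parameter_id))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def sample_draws(
    config: ModelConfig, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorised draws for every parameter carrying a distribution.

    Each distributed parameter is sampled once per iteration (shared
    parameters are therefore correlated across arms by construction);
    ``fixed`` distributions repeat the base value.
    """
    draws: dict[str, np.ndarray] = {}
    for pid, p in config.parameters.items():
        if p.distribution is None:
            continue
        d = p.distribution
        if d.family == "gamma_scale":
            draws[pid] = rng.gamma(shape=d.p1, scale=d.p2, size=n)
        elif d.family == "beta":
            draws[pid] = rng.beta(d.p1, d.p2, size=n)
        else:  # fixed
            draws[pid] = np.full(n, d.p1)
    return draws


def sample_draw(config: ModelConfig, rng: np.random.Generator) -> dict[str, float]:
    """One parameter assignment (a single probabilistic iteration)."""
    return {pid: float(v[0]) for pid, v in sample_draws(config, 1, rng).items()}


@dataclass(frozen=True)
class PsaOutput:
    """Per-iteration discounted (cost, QALY) pairs per arm."""

    labels: tuple[str, str]
    costs: np.ndarray  # (iterations, 2): intervention, comparator
    qalys: np.ndarray
    seed: int
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def iterations(self) -> int:
        return self.costs.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs[:, 0] - self.costs[:, 1]

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qalys[:, 0] - self.qalys[:, 1]

    def nmb(self, wtp: float) -> np.ndarray:
        """Per-arm net monetary benefit, shape (iterations, 2)."""
        return wtp * self.qalys - self.costs

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, label in enumerate(self.labels):
            frames.append(pd.DataFrame({
                "iteration": np.arange(self.iterations),
                "arm": label,
                "cost": self.costs[:, j],
                "qalys": self.qalys[:, j],
            }))
        return pd.concat(frames, ignore_index=True)

    def plane_frame(self) -> pd.DataFrame:
        """Cost-effectiveness plane scatter data (incremental pairs)."""
        return pd.DataFrame({
            "iteration": np.arange(self.iterations),
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
        })


def run_psa(
    config: ModelConfig,
    iterations: int | None = None,
    seed: int | None = None,
) -> PsaOutput:
    """Monte Carlo propagation of parameter uncertainty through both arms.

    Per iteration: one joint parameter draw, both arms accrued over
    their (fixed) deterministic traces.  Reproducible given ``seed``
    (defaults to the configuration's ``rng_seed``).
    """
    if iterations is None:
        iterations = config.settings.psa_iterations
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if seed is None:
        seed = config.settings.rng_seed
    rng = rng_stream(seed, "psa")
    draws = sample_draws(config, iterations, rng)

    traces: dict[str, CohortTrace] = {}
    for arm in config.arms:
        matrices = expand_matrices(arm.transitions)
        traces[arm.label] = run_cohort(
            initial_occupancy(config.settings.initial_hd_fraction),
            matrices,
            config.settings.horizon_cycles,
        )

    costs = np.empty((iterations, 2))
    qalys = np.empty((iterations, 2))
    for i in range(iterations):
        overrides = {pid: v[i] for pid, v in draws.items()}
        for j, arm in enumerate(config.arms):
            out = run_arm(config, arm, overrides, trace=traces[arm.label])
            costs[i, j] = out.cost
            qalys[i, j] = out.qalys
    return PsaOutput(
        labels=(config.arms[0].label, config.arms[1].label),
        costs=costs, qalys=qalys, seed=int(seed), draws=draws,
    )


# ---------------------------------------------------------------------------
# CEAC and EVPI
# ---------------------------------------------------------------------------

def default_wtp_grid(wtp: float = 217113.0, stop: float = 400000.0,
                     step: float = 5000.0) -> np.ndarray:
    """0 .. ``stop`` in ``step`` increments, always including ``wtp``."""
    grid = np.arange(0.0, stop + step / 2, step)
    return np.unique(np.append(grid, wtp))


def ceac(draws: PsaOutput, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability the intervention is cost-effective at each threshold.

    At each willingness-to-pay the probability is the fraction of
    iterations with strictly positive incremental net monetary benefit
    (ties count as not cost-effective).
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValidationError("wtp grid must be non-empty")
    dc, dq = draws.delta_cost, draws.delta_qalys
    probs = [(w * dq - dc > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probs})


def ceac_point(draws: PsaOutput, wtp: float) -> tuple[float, tuple[float, float]]:
    """CEAC value at one threshold with a binomial 95% interval."""
    p = float((wtp * draws.delta_qalys - draws.delta_cost > 0).mean())
    half = 1.96 * np.sqrt(p * (1 - p) / draws.iterations)
    return p, (max(0.0, p - half), min(1.0, p + half))


def evpi(
    draws: PsaOutput,
    wtp_grid: Sequence[float],
    cohort_size: int | None = None,
) -> pd.DataFrame:
    """Expected value of perfect information per threshold.

    Per person: mean over iterations of the best attainable net monetary
    benefit minus the net monetary benefit of the best strategy on
    average, E[max_arm NMB] - max_arm E[NMB]; non-negative by Jensen's
    inequality and zero when nothing is uncertain.  The population value
    scales by the beneficiary cohort size.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValidationError("wtp grid must be non-empty")
    n_cohort = 1 if cohort_size is None else int(cohort_size)
    rows = []
    for w in wtp_grid:
        nmb = draws.nmb(w)
        per_person = float(nmb.max(axis=1).mean() - nmb.mean(axis=0).max())
        # snap float-summation residue (degenerate draws) to an exact zero
        scale = max(1.0, float(np.abs(nmb).max()))
        if per_person < 1e-9 * scale:
            per_person = 0.0
        rows.append({"wtp": w, "per_person": per_person,
                     "population": per_person * n_cohort})
    return pd.DataFrame(rows)
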