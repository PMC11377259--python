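"""Sensitivity analyses for the two-arm decision tree.

One-way deterministic sensitivity analysis (DSA, tornado): each parameter is
moved to its low and high value with all others held at base; perturbing a
conditional time-bin probability rebalances only the residual (final) bin so
the conditional set still sums to one.

Probabilistic sensitivity analysis (PSA): all parameters are sampled jointly —
probabilities from beta(α, β), utilities from moment-matched betas, costs from
moment-matched gammas — and the tree is re-evaluated per draw, yielding a cloud
of (ΔC, ΔE) points on the cost-effectiveness plane.  By default utilities are
sampled independently for each arm's branches; ``utility_sampling: shared`` in
the configuration uses one utility draw for both arms.  Sampled conditional
bin sets whose listed bins exceed one are resampled (up to 100 attempts) rather
than truncated, preserving the beta marginals; the resample frequency is logged.

The cost-effectiveness acceptability curve (CEAC) reports, per willingness-to-
pay value λ, the fraction of draws with positive incremental net monetary
benefit λ·ΔE − ΔC.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import tree
from .params_io import (
    ArmParams,
    ConfigError,
    ModelConfig,
    build_distribution,
    make_arm_spec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterRange",
    "TornadoEntry",
    "PSADraw",
    "CEACPoint",
    "default_dsa_ranges",
    "one_way_dsa",
    "tornado_table",
    "sample_parameters",
    "run_psa",
    "psa_table",
    "ceac",
    "ceac_table",
    "classify_quadrant",
    "DEFAULT_WTP_GRID",
]

_MAX_RESAMPLE = 100
#: default CEAC grid: 0 to 150,000 CNY/QALD in 1,000-CNY steps
DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 150_001, 1_000))


@dataclass(frozen=True)
class ParameterRange:
    """One DSA parameter with its low/base/high values."""

    parameter: str
    low: float
    base: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ConfigError(
                f"{self.parameter}: requires low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """ICERs at a parameter's range ends; ``width`` is the ICER span when both
    ends have a defined ICER, infinite when an end flips to a dominance
    classification (those entries rank first)."""

    parameter: str
    low: float
    high: float
    icer_at_low: float | str
    icer_at_high: float | str
    width: float


@dataclass(frozen=True)
class PSADraw:
    """One PSA iteration: sampled parameter values and its incremental outcome."""

    iteration: int
    values: dict[str, float]
    delta_cost: float
    delta_effect: float
    quadrant: str


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_ce: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability_ce <= 1.0:
            raise ValueError("probability_ce outside [0, 1]")


def classify_quadrant(delta_cost: float, delta_effect: float) -> str:
    """CE-plane quadrant of an incremental outcome.

    NE: costlier and more effective; SE: cheaper (or free) and more effective
    (dominant); NW: costlier with no effectiveness gain (dominated); SW:
    cheaper with no gain.  ΔE = 0 counts as "no gain" (dominance-conservative).
    """
    if delta_effect > 0:
        return "NE" if delta_cost > 0 else "SE"
    return "NW" if delta_cost > 0 else "SW"


# ---------------------------------------------------------------------------
# mutable working view of the model parameters


@dataclass
class _Working:
    """Scalar parameter values of a configuration, mutable for DSA/PSA."""

    config: ModelConfig
    cost: dict[str, float]
    p_pf: dict[str, float]
    p_fmbs: dict[str, float]
    pf_bins: dict[str, list[float]]
    fmbs_bins: dict[str, list[float]]
    pf_utility: dict[str, dict[int, float]]  # per arm name
    ti_utility: dict[str, float]

    @classmethod
    def from_config(cls, config: ModelConfig) -> "_Working":
        cost, p_pf, p_fmbs, pfb, fmb, pfu, tiu = {}, {}, {}, {}, {}, {}, {}
        for arm in config.arms():
            cost[arm.name] = arm.dose_cost.base
            p_pf[arm.name] = arm.p_pf.value
            p_fmbs[arm.name] = arm.p_fmbs.value
            pfb[arm.name] = arm.bin_values("pf")
            fmb[arm.name] = arm.bin_values("fmbs")
            pfu[arm.name] = {t: u.base for t, u in config.pf_utilities.items()}
            tiu[arm.name] = config.ti_utility.base
        return cls(config, cost, p_pf, p_fmbs, pfb, fmb, pfu, tiu)

    def arm_spec(self, arm: ArmParams) -> tree.ArmSpec:
        cfg = self.config
        return make_arm_spec(
            name=arm.name,
            dose_cost=self.cost[arm.name],
            p_pf=self.p_pf[arm.name],
            p_fmbs=self.p_fmbs[arm.name],
            pf_bin_probs=self.pf_bins[arm.name],
            fmbs_bin_probs=self.fmbs_bins[arm.name],
            pf_utilities=self.pf_utility[arm.name],
            ti_utility=self.ti_utility[arm.name],
            mbs_factor=cfg.mbs_utility_factor,
            time_bins=cfg.time_bins,
        )

    def evaluate(self) -> tree.IncrementalResult:
        cfg = self.config
        t = tree.evaluate_arm(self.arm_spec(cfg.treatment), cfg.horizon_hours)
        c = tree.evaluate_arm(self.arm_spec(cfg.comparator), cfg.horizon_hours)
        return tree.incremental(t, c)


def _clip01(value: float, parameter: str) -> float:
    if value < 0.0 or value > 1.0:
        clipped = min(1.0, max(0.0, value))
        logger.warning("%s: value %.6g clipped to %.6g", parameter, value, clipped)
        return clipped
    return value


def _apply(work: _Working, parameter: str, value: float) -> None:
    """Set one parameter by id, rebalancing residual bins as needed.

    Ids: ``<arm>.cost``, ``<arm>.p_pf``, ``<arm>.p_fmbs``,
    ``<arm>.pf_bin_<min>``, ``<arm>.fmbs_bin_<min>``,
    ``<arm>.fmbs_bins_grouped`` (scales all listed FMBS bins jointly),
    ``utility.pf_<min>``, ``utility.ti``.
    """
    scope, _, field_id = parameter.partition(".")
    if scope == "utility":
        value = _clip01(value, parameter)
        if field_id == "ti":
            for name in work.ti_utility:
                work.ti_utility[name] = value
            return
        if field_id.startswith("pf_"):
            t = int(field_id[3:])
            for name in work.pf_utility:
                if t not in work.pf_utility[name]:
                    raise ConfigError(f"unknown DSA parameter {parameter!r}")
                work.pf_utility[name][t] = value
            return
        raise ConfigError(f"unknown DSA parameter {parameter!r}")

    if scope not in work.cost:
        raise ConfigError(f"unknown DSA parameter {parameter!r}: no arm {scope!r}")
    if field_id == "cost":
        if value < 0:
            logger.warning("%s: negative cost %.6g clipped to 0", parameter, value)
            value = 0.0
        work.cost[scope] = value
        return
    if field_id in ("p_pf", "p_fmbs"):
        value = _clip01(value, parameter)
        other = work.p_fmbs[scope] if field_id == "p_pf" else work.p_pf[scope]
        if value + other > 1.0:
            logger.warning(
                "%s: value %.6g clipped to keep principal-state mass <= 1",
                parameter, value,
            )
            value = 1.0 - other
        (work.p_pf if field_id == "p_pf" else work.p_fmbs)[scope] = value
        return
    listed = list(work.config.time_bins[:-1])
    if field_id == "fmbs_bins_grouped":
        # joint scaling of the listed FMBS bins; residual rebalances
        bins = work.fmbs_bins[scope]
        scaled = [b * value for b in bins]
        if sum(scaled) > 1.0:
            logger.warning("%s: scaled bins exceed 1; renormalized", parameter)
            scaled = [b / sum(scaled) for b in scaled]
        work.fmbs_bins[scope] = scaled
        return
    for state, key in (("pf", "pf_bin_"), ("fmbs", "fmbs_bin_")):
        if field_id.startswith(key):
            t = int(field_id[len(key):])
            if t not in listed:
                raise ConfigError(
                    f"unknown DSA parameter {parameter!r}: bin {t} is not a listed bin"
                )
            value = _clip01(value, parameter)
            bins = work.pf_bins[scope] if state == "pf" else work.fmbs_bins[scope]
            idx = listed.index(t)
            rest = sum(b for i, b in enumerate(bins) if i != idx)
            if value + rest > 1.0:
                logger.warning(
                    "%s: value %.6g clipped so conditional bins stay <= 1",
                    parameter, value,
                )
                value = 1.0 - rest
            bins[idx] = value
            return
    raise ConfigError(f"unknown DSA parameter {parameter!r}")


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis


def default_dsa_ranges(config: ModelConfig) -> list[ParameterRange]:
    """Default one-way ranges: configured low/high for utilities and costs,
    ±10% of base for every probability (residual bins rebalance)."""
    ranges: list[ParameterRange] = []
    for arm in config.arms():
        c = arm.dose_cost
        if c.high > c.low:
            ranges.append(ParameterRange(f"{arm.name}.cost", c.low, c.base, c.high))
        for pid, param in (("p_pf", arm.p_pf), ("p_fmbs", arm.p_fmbs)):
            ranges.append(_pm10(f"{arm.name}.{pid}", param.value))
        for t in config.time_bins[:-1]:
            ranges.append(_pm10(f"{arm.name}.pf_bin_{t}", arm.pf_bins[t].value))
            ranges.append(_pm10(f"{arm.name}.fmbs_bin_{t}", arm.fmbs_bins[t].value))
    for t, u in sorted(config.pf_utilities.items()):
        ranges.append(ParameterRange(f"utility.pf_{t}", u.low, u.base, u.high))
    u = config.ti_utility
    ranges.append(ParameterRange("utility.ti", u.low, u.base, u.high))
    return ranges


def _pm10(parameter: str, base: float) -> ParameterRange:
    return ParameterRange(parameter, 0.9 * base, base, min(1.0, 1.1 * base))


def _icer_or_flag(inc: tree.IncrementalResult) -> float | str:
    if inc.classification == "icer_defined":
        return inc.icer  # type: ignore[return-value]
    return inc.classification


def one_way_dsa(
    config: ModelConfig,
    ranges: Optional[Sequence[ParameterRange]] = None,
    *,
    include_grouped_fmbs: bool = False,
) -> list[TornadoEntry]:
    """Tornado analysis: recompute the ICER at each parameter's low and high
    with all others at base; entries sorted by descending ICER width.

    ``include_grouped_fmbs`` adds, per arm, an entry scaling all listed FMBS
    time-bin probabilities jointly by ±10% (a grouped variant of the
    single-parameter bin entries).
    """
    if ranges is None:
        ranges = default_dsa_ranges(config)
        if include_grouped_fmbs:
            ranges = list(ranges) + [
                ParameterRange(f"{arm.name}.fmbs_bins_grouped", 0.9, 1.0, 1.1)
                for arm in config.arms()
            ]
    entries = []
    for rng_ in ranges:
        icers = []
        for value in (rng_.low, rng_.high):
            work = _Working.from_config(config)
            _apply(work, rng_.parameter, value)
            icers.append(_icer_or_flag(work.evaluate()))
        lo, hi = icers
        if isinstance(lo, float) and isinstance(hi, float):
            width = abs(hi - lo)
        else:
            width = math.inf
        entries.append(TornadoEntry(rng_.parameter, rng_.low, rng_.high, lo, hi, width))
    entries.sort(key=lambda e: (-e.width, e.parameter))
    return entries


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"parameter": e.parameter, "low": e.low, "high": e.high,
             "icer_at_low": e.icer_at_low, "icer_at_high": e.icer_at_high,
             "width": e.width}
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class SampledParameters:
    """One joint draw of all model parameters, evaluable through the tree."""

    treatment: tree.ArmSpec
    comparator: tree.ArmSpec
    values: dict[str, float]
    resamples: int = 0


def _sample_bins(
    params: dict[int, "object"], rng: np.random.Generator, label: str
) -> tuple[list[float], int]:
    dists = [params[t].distribution for t in sorted(params)]
    resamples = 0
    for _ in range(_MAX_RESAMPLE):
        draw = [float(d.sample(rng)) for d in dists]
        if sum(draw) <= 1.0:
            return draw, resamples
        resamples += 1
    raise ConfigError(
        f"{label}: sampled conditional bins exceeded 1 in {_MAX_RESAMPLE} attempts"
    )


def _utility_distributions(config: ModelConfig):
    pf = {t: build_distribution(u) for t, u in config.pf_utilities.items()}
    ti = build_distribution(config.ti_utility)
    return pf, ti


def sample_parameters(
    config: ModelConfig, rng: np.random.Generator
) -> SampledParameters:
    """Draw one joint parameter sample and assemble both arms.

    Probabilities come from their beta distributions (renormalized against the
    residual bin, resampling when the listed bins exceed one); utilities from
    their moment-matched betas — independently per arm unless the configuration
    requests shared sampling; costs from their moment-matched gammas.
    """
    values: dict[str, float] = {}
    resamples = 0
    pf_dists, ti_dist = _utility_distributions(config)

    def draw_utilities() -> tuple[dict[int, float], float]:
        pf_u = {t: float(pf_dists[t].sample(rng)) for t in config.time_bins}
        return pf_u, float(ti_dist.sample(rng))

    shared = None
    if config.utility_sampling == "shared":
        shared = draw_utilities()
        for t, u in shared[0].items():
            values[f"utility.pf_{t}"] = u
        values["utility.ti"] = shared[1]

    specs = {}
    for arm in config.arms():
        name = arm.name
        for _ in range(_MAX_RESAMPLE + 1):
            p_pf = float(arm.p_pf.distribution.sample(rng))
            p_fmbs = float(arm.p_fmbs.distribution.sample(rng))
            if p_pf + p_fmbs <= 1.0:
                break
            resamples += 1
        else:
            raise ConfigError(
                f"{name}: sampled principal-state probabilities exceeded 1 in "
                f"{_MAX_RESAMPLE} attempts"
            )
        pf_bins, r1 = _sample_bins(arm.pf_bins, rng, f"{name}.pain_freedom_bins")
        fmbs_bins, r2 = _sample_bins(arm.fmbs_bins, rng, f"{name}.fmbs_bins")
        resamples += r1 + r2
        cost = float(arm.cost_distribution.sample(rng))
        if shared is not None:
            pf_u, ti_u = shared
        else:
            pf_u, ti_u = draw_utilities()
            for t, u in pf_u.items():
                values[f"{name}.utility.pf_{t}"] = u
            values[f"{name}.utility.ti"] = ti_u
        values[f"{name}.cost"] = cost
        values[f"{name}.p_pf"] = p_pf
        values[f"{name}.p_fmbs"] = p_fmbs
        for t, v in zip(sorted(arm.pf_bins), pf_bins):
            values[f"{name}.pf_bin_{t}"] = v
        for t, v in zip(sorted(arm.fmbs_bins), fmbs_bins):
            values[f"{name}.fmbs_bin_{t}"] = v
        specs[name] = make_arm_spec(
            name=name,
            dose_cost=cost,
            p_pf=p_pf,
            p_fmbs=p_fmbs,
            pf_bin_probs=pf_bins,
            fmbs_bin_probs=fmbs_bins,
            pf_utilities=pf_u,
            ti_utility=ti_u,
            mbs_factor=config.mbs_utility_factor,
            time_bins=config.time_bins,
        )
    return SampledParameters(
        treatment=specs[config.treatment.name],
        comparator=specs[config.comparator.name],
        values=values,
        resamples=resamples,
    )


def run_psa(
    config: ModelConfig, n_iterations: int, seed: Optional[int] = None
) -> list[PSADraw]:
    """Monte Carlo PSA: one joint parameter draw and tree evaluation per
    iteration; reproducible given ``seed``."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    draws: list[PSADraw] = []
    total_resamples = 0
    for i in range(n_iterations):
        sample = sample_parameters(config, rng)
        total_resamples += sample.resamples
        t = tree.evaluate_arm(sample.treatment, config.horizon_hours)
        c = tree.evaluate_arm(sample.comparator, config.horizon_hours)
        dc, de = t.cost - c.cost, t.effect - c.effect
        draws.append(
            PSADraw(
                iteration=i,
                values=sample.values,
                delta_cost=dc,
                delta_effect=de,
                quadrant=classify_quadrant(dc, de),
            )
        )
    logger.info(
        "PSA: %d iterations, %d constraint resamples", n_iterations, total_resamples
    )
    return draws


def psa_table(draws: Sequence[PSADraw]) -> pd.DataFrame:
    """PSA draws as a table: outcome columns first, then sampled parameters."""
    rows = []
    for d in draws:
        row = {"iteration": d.iteration, "delta_cost": d.delta_cost,
               "delta_effect": d.delta_effect, "quadrant": d.quadrant}
        row.update(d.values)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# acceptability curve


def ceac(
    draws: Sequence[PSADraw], wtp_grid: Sequence[float] = DEFAULT_WTP_GRID
) -> list[CEACPoint]:
    """Probability the treatment is cost-effective per WTP value: the fraction
    of draws with positive incremental net monetary benefit λ·ΔE − ΔC.  The
    comparator's probability is the complement."""
    if len(draws) == 0:
        raise ValueError("ceac requires at least one PSA draw")
    dc = np.array([d.delta_cost for d in draws])
    de = np.array([d.delta_effect for d in draws])
    return [
        CEACPoint(float(l), float(np.mean(l * de - dc > 0))) for l in wtp_grid
    ]


def ceac_table(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"wtp": p.wtp, "probability_treatment": p.probability_ce,
             "probability_comparator": 1.0 - p.probability_ce}
            for p in points
        ]
    )
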