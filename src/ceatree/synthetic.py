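"""Synthetic two-arm acute-treatment trials with known ground truth.

Emulates the endpoint structure of a randomized acute-migraine trial with two
co-primary 2-hour endpoints — pain freedom (PF) and freedom from the most
bothersome symptom (FMBS) — plus time-to-relief assessments at 15, 30, 45, 60,
90 and 120 minutes.  Each patient lands in exactly one principal state
(PF, FMBS or treatment ineffectiveness: the tree's states are mutually
exclusive), so per-arm state membership is multinomial and each 2-hour
endpoint count is marginally binomial; responders are then allocated across
the six time bins multinomially.

Counts are emitted in the input-table layout (responders α, non-responders β
per row, with the final time bin left to complement-derivation), so simulated
trials flow through the same configuration loader as real inputs and the full
pipeline — parameter derivation, tree evaluation, DSA/PSA — can be exercised
end-to-end against known truth.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .params_io import (
    DEFAULT_TIME_BINS,
    ConfigError,
    ModelConfig,
    ResponderCounts,
    model_config_from_dict,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ArmTruth",
    "TrialScenario",
    "ArmCounts",
    "TrialCounts",
    "simulate_trial",
    "counts_to_config_dict",
    "generate_config",
    "scenario_from_config",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ArmTruth:
    """True outcome probabilities and size of one trial arm.

    ``pf_bin_probs`` / ``fmbs_bin_probs`` give the conditional time-bin
    distribution over all six bins (must sum to one).
    """

    name: str
    n: int
    p_pf: float
    p_fmbs: float
    pf_bin_probs: tuple[float, ...]
    fmbs_bin_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError(f"arm {self.name!r}: size must be positive")
        if not (0.0 <= self.p_pf <= 1.0 and 0.0 <= self.p_fmbs <= 1.0):
            raise ConfigError(f"arm {self.name!r}: endpoint probabilities outside [0, 1]")
        if self.p_pf + self.p_fmbs > 1.0 + _SUM_TOL:
            raise ConfigError(f"arm {self.name!r}: p_pf + p_fmbs exceeds 1")
        for label, probs in (("pf_bin_probs", self.pf_bin_probs),
                             ("fmbs_bin_probs", self.fmbs_bin_probs)):
            if any(p < 0 for p in probs):
                raise ConfigError(f"arm {self.name!r}: negative {label}")
            if abs(math.fsum(probs) - 1.0) > 1e-6:
                raise ConfigError(f"arm {self.name!r}: {label} must sum to 1")


@dataclass(frozen=True)
class TrialScenario:
    """A full two-arm trial specification with ground-truth parameters."""

    treatment: ArmTruth
    comparator: ArmTruth
    time_bins: tuple[int, ...] = DEFAULT_TIME_BINS
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for arm in (self.treatment, self.comparator):
            if len(arm.pf_bin_probs) != len(self.time_bins):
                raise ConfigError(
                    f"arm {arm.name!r}: expected {len(self.time_bins)} bin probabilities"
                )


@dataclass(frozen=True)
class ArmCounts:
    """Simulated responder counts of one arm in the input-table layout.

    Bin counts are conditional on the 2-hour responders of the state and cover
    the non-residual bins only (the final bin is the complement).  Bin maps are
    ``None`` when the state has no responders, in which case no conditional
    split exists.
    """

    name: str
    n: int
    pf_2h: ResponderCounts
    fmbs_2h: ResponderCounts
    pf_bins: Optional[dict[int, ResponderCounts]]
    fmbs_bins: Optional[dict[int, ResponderCounts]]


@dataclass(frozen=True)
class TrialCounts:
    treatment: ArmCounts
    comparator: ArmCounts


def _simulate_arm(
    arm: ArmTruth, time_bins: Sequence[int], rng: np.random.Generator
) -> ArmCounts:
    # one multinomial over the three mutually exclusive principal states
    n_pf, n_fmbs, _ = rng.multinomial(
        arm.n, [arm.p_pf, arm.p_fmbs, max(0.0, 1.0 - arm.p_pf - arm.p_fmbs)]
    )

    def split(n_state: int, probs: Sequence[float], label: str):
        if n_state == 0:
            logger.info("arm %s: no %s responders; bin split undefined", arm.name, label)
            return None
        counts = rng.multinomial(n_state, probs)
        return {
            int(t): ResponderCounts(int(c), int(n_state - c),
                                    label=f"{arm.name}.{label}.{t}")
            for t, c in zip(time_bins[:-1], counts[:-1])
        }

    return ArmCounts(
        name=arm.name,
        n=arm.n,
        pf_2h=ResponderCounts(int(n_pf), int(arm.n - n_pf), label=f"{arm.name}.pf_2h"),
        fmbs_2h=ResponderCounts(int(n_fmbs), int(arm.n - n_fmbs),
                                label=f"{arm.name}.fmbs_2h"),
        pf_bins=split(int(n_pf), arm.pf_bin_probs, "pf"),
        fmbs_bins=split(int(n_fmbs), arm.fmbs_bin_probs, "fmbs"),
    )


def simulate_trial(
    scenario: TrialScenario,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> TrialCounts:
    """Simulate one trial: multinomial state membership per arm, multinomial
    time-bin allocation of responders; reproducible given a seed.

    ``seed`` overrides ``scenario.seed`` and may be a Generator.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(scenario.seed if seed is None else seed)
    return TrialCounts(
        treatment=_simulate_arm(scenario.treatment, scenario.time_bins, rng),
        comparator=_simulate_arm(scenario.comparator, scenario.time_bins, rng),
    )


def _counts_entry(c: ResponderCounts) -> dict:
    return {"successes": c.successes, "failures": c.failures}


def _arm_dict(counts: ArmCounts, template_arm) -> dict:
    if counts.pf_bins is None or counts.fmbs_bins is None:
        raise ConfigError(
            f"arm {counts.name!r}: a principal state has no responders, so its "
            "conditional time-bin probabilities cannot be derived"
        )
    cost = template_arm.dose_cost
    return {
        "name": counts.name,
        "dose_cost": {"base": cost.base, "low": cost.low, "high": cost.high,
                      "sd": cost.sd},
        "pain_freedom_2h": _counts_entry(counts.pf_2h),
        "fmbs_2h": _counts_entry(counts.fmbs_2h),
        "pain_freedom_bins": {t: _counts_entry(c) for t, c in counts.pf_bins.items()},
        "fmbs_bins": {t: _counts_entry(c) for t, c in counts.fmbs_bins.items()},
    }


def counts_to_config_dict(counts: TrialCounts, template: ModelConfig) -> dict:
    """Merge simulated counts with a template's utilities, costs and settings
    into a raw configuration mapping (the same schema the loader reads)."""
    utilities = {
        "pain_freedom": {
            t: {"base": u.base, "low": u.low, "high": u.high, "sd": u.sd}
            for t, u in template.pf_utilities.items()
        },
        "sustained_pain": {
            "base": template.ti_utility.base, "low": template.ti_utility.low,
            "high": template.ti_utility.high, "sd": template.ti_utility.sd,
        },
    }
    return {
        "name": "synthetic-trial",
        "horizon_hours": template.horizon_hours,
        "wtp_per_qald": template.wtp,
        "mbs_utility_factor": template.mbs_utility_factor,
        "time_bins_min": list(template.time_bins),
        "arms": {
            "treatment": _arm_dict(counts.treatment, template.treatment),
            "comparator": _arm_dict(counts.comparator, template.comparator),
        },
        "utilities": utilities,
        "psa": {"utility_sampling": template.utility_sampling},
    }


def generate_config(
    scenario: TrialScenario,
    template: ModelConfig,
    seed: Optional[Union[int, np.random.Generator]] = None,
    counts: Optional[TrialCounts] = None,
) -> ModelConfig:
    """Simulate a trial (or take ``counts``) and build a complete, validated
    model configuration using the template's utilities, costs and settings."""
    if counts is None:
        counts = simulate_trial(scenario, seed=seed)
    return model_config_from_dict(counts_to_config_dict(counts, template))


def scenario_from_config(
    config: ModelConfig,
    n_treatment: int = 666,
    n_comparator: int = 674,
    seed: Optional[int] = None,
) -> TrialScenario:
    """Scenario whose ground truth equals a configuration's derived
    probabilities; default arm sizes match the source trial's 2-hour endpoint
    denominators (666 treatment, 674 placebo)."""
    from .params_io import residual_probability

    def truth(arm_params, n: int) -> ArmTruth:
        pf5 = arm_params.bin_values("pf")
        fm5 = arm_params.bin_values("fmbs")
        return ArmTruth(
            name=arm_params.name,
            n=n,
            p_pf=arm_params.p_pf.value,
            p_fmbs=arm_params.p_fmbs.value,
            pf_bin_probs=tuple(pf5) + (residual_probability(pf5),),
            fmbs_bin_probs=tuple(fm5) + (residual_probability(fm5),),
        )

    return TrialScenario(
        treatment=truth(config.treatment, n_treatment),
        comparator=truth(config.comparator, n_comparator),
        time_bins=config.time_bins,
        seed=seed,
    )
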