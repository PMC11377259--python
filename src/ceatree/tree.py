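"""Deterministic evaluation of the two-arm acute-treatment decision tree.

The tree has one chance node per arm splitting patients into three principal
health states — pain freedom (PF), freedom from the most bothersome symptom
(FMBS), and treatment ineffectiveness (TI, sustained pain) — with PF and FMBS
each subdivided into six time-to-relief bins (15, 30, 45, 60, 90, 120 minutes
post-dose).  Each of the 13 terminal branches carries a utility that applies
to the whole horizon; effectiveness is expressed in quality-adjusted life days
(QALD = expected utility x horizon_hours / 24).  Cost is the single per-dose
drug price: the model carries no adverse-event, recurrence or indirect costs,
and applies no discounting over its 2-hour horizon.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "TimedBranch",
    "ArmSpec",
    "ArmResult",
    "IncrementalResult",
    "BaseCaseResult",
    "expected_utility",
    "qald",
    "expected_cost",
    "evaluate_arm",
    "incremental",
    "net_monetary_benefit",
    "threshold_price",
    "evaluate_base_case",
]

_PROB_TOL = 1e-9
_ZERO_TOL = 1e-12


class ModelError(ValueError):
    """Raised when an arm or result violates a structural invariant."""


@dataclass(frozen=True)
class TimedBranch:
    """A terminal outcome: a principal state reached within a given time bin."""

    time_min: int
    probability: float  # conditional on the principal state
    utility: float

    def __post_init__(self) -> None:
        if not -_PROB_TOL <= self.probability <= 1 + _PROB_TOL:
            raise ModelError(
                f"branch probability {self.probability!r} at {self.time_min} min "
                "is outside [0, 1]"
            )
        if not 0.0 <= self.utility <= 1.0:
            raise ModelError(
                f"branch utility {self.utility!r} at {self.time_min} min is outside [0, 1]"
            )


@dataclass(frozen=True)
class ArmSpec:
    """One comparator arm of the tree, fully specified by base (or sampled) values.

    ``p_pf`` and ``p_fmbs`` are the 2-hour probabilities of the PF and FMBS
    principal states; treatment ineffectiveness takes the residual mass.  Each
    principal state carries six conditional time-bin branches whose
    probabilities sum to one.
    """

    name: str
    dose_cost: float
    p_pf: float
    p_fmbs: float
    pf_branches: tuple[TimedBranch, ...]
    fmbs_branches: tuple[TimedBranch, ...]
    ti_utility: float

    def __post_init__(self) -> None:
        if self.dose_cost < 0:
            raise ModelError(f"arm {self.name!r}: negative dose cost {self.dose_cost!r}")
        for label, p in (("p_pf", self.p_pf), ("p_fmbs", self.p_fmbs)):
            if not -_PROB_TOL <= p <= 1 + _PROB_TOL:
                raise ModelError(f"arm {self.name!r}: {label}={p!r} outside [0, 1]")
        if self.p_pf + self.p_fmbs > 1 + _PROB_TOL:
            raise ModelError(
                f"arm {self.name!r}: p_pf + p_fmbs = {self.p_pf + self.p_fmbs!r} exceeds 1"
            )
        if not 0.0 <= self.ti_utility <= 1.0:
            raise ModelError(f"arm {self.name!r}: ti_utility outside [0, 1]")
        for state, branches in (("PF", self.pf_branches), ("FMBS", self.fmbs_branches)):
            total = math.fsum(b.probability for b in branches)
            if abs(total - 1.0) > _PROB_TOL:
                raise ModelError(
                    f"arm {self.name!r}: {state} conditional bin probabilities sum to "
                    f"{total!r}, expected 1"
                )

    @property
    def p_ti(self) -> float:
        """Probability of treatment ineffectiveness (residual principal state)."""
        return max(0.0, 1.0 - self.p_pf - self.p_fmbs)


@dataclass(frozen=True)
class ArmResult:
    """Expected cost (CNY) and expected effectiveness (QALD) of one arm."""

    name: str
    cost: float
    effect: float


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison treatment minus comparator on the CE plane.

    ``classification`` is one of ``icer_defined`` (ICER meaningful: both
    differences share a sign), ``dominant`` (cheaper and at least as
    effective), ``dominated`` (costlier and at most as effective) or
    ``equivalent`` (both differences numerically zero).
    """

    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    classification: str


def expected_utility(arm: ArmSpec) -> float:
    """Probability-weighted utility over the 13 terminal branches of one arm."""
    pf = math.fsum(b.probability * b.utility for b in arm.pf_branches)
    fmbs = math.fsum(b.probability * b.utility for b in arm.fmbs_branches)
    return arm.p_pf * pf + arm.p_fmbs * fmbs + arm.p_ti * arm.ti_utility


def qald(expected_utility: float, horizon_hours: float) -> float:
    """Quality-adjusted life days accrued over the horizon.

    The terminal-state utility applies to the whole horizon, so
    QALD = utility x horizon_hours / 24.
    """
    if not 0.0 <= expected_utility <= 1.0:
        raise ModelError(f"expected utility {expected_utility!r} outside [0, 1]")
    if horizon_hours <= 0:
        raise ModelError(f"horizon must be positive, got {horizon_hours!r}")
    return expected_utility * horizon_hours / 24.0


def expected_cost(arm: ArmSpec) -> float:
    """Expected cost of one arm: the single per-dose price (no other components)."""
    return arm.dose_cost


def evaluate_arm(arm: ArmSpec, horizon_hours: float) -> ArmResult:
    return ArmResult(
        name=arm.name,
        cost=expected_cost(arm),
        effect=qald(expected_utility(arm), horizon_hours),
    )


def incremental(
    treatment: ArmResult, comparator: ArmResult, *, atol: float = _ZERO_TOL
) -> IncrementalResult:
    """Classify (ΔC, ΔE) = treatment − comparator on the cost-effectiveness plane.

    Degenerate cases return a classification, never a division failure: the
    ICER is reported only when both differences are non-zero with the same
    sign (more costly and more effective, or the reverse).
    """
    dc = treatment.cost - comparator.cost
    de = treatment.effect - comparator.effect
    dc_zero, de_zero = abs(dc) <= atol, abs(de) <= atol
    if dc_zero and de_zero:
        return IncrementalResult(dc, de, None, "equivalent")
    if dc <= atol and de >= -atol:
        return IncrementalResult(dc, de, None, "dominant")
    if dc >= -atol and de <= atol:
        return IncrementalResult(dc, de, None, "dominated")
    return IncrementalResult(dc, de, dc / de, "icer_defined")


def net_monetary_benefit(result: ArmResult, wtp: float) -> float:
    """NMB = wtp x effect − cost; the NMB ordering of two arms is equivalent to
    the ICER-versus-WTP decision rule."""
    if wtp < 0:
        raise ModelError(f"willingness-to-pay must be non-negative, got {wtp!r}")
    return wtp * result.effect - result.cost


def threshold_price(config, wtp: Optional[float] = None) -> float:
    """Per-dose treatment price at which the ICER equals the WTP threshold.

    With a fixed comparator and effects independent of price, the ICER is
    linear in the treatment price, so the threshold solves in closed form:
    price = comparator_cost + wtp x ΔE.  Requires ΔE > 0 at the configured
    parameters; otherwise no positive-price solution exists.
    """
    if wtp is None:
        wtp = config.wtp
    if wtp < 0:
        raise ModelError(f"willingness-to-pay must be non-negative, got {wtp!r}")
    t = evaluate_arm(config.treatment_spec(), config.horizon_hours)
    c = evaluate_arm(config.comparator_spec(), config.horizon_hours)
    de = t.effect - c.effect
    if de <= 0:
        raise ModelError(
            "threshold price undefined: treatment is not more effective than the "
            f"comparator (ΔE = {de!r})"
        )
    return c.cost + wtp * de


@dataclass(frozen=True)
class BaseCaseResult:
    """Deterministic evaluation of a full model configuration."""

    treatment: ArmResult
    comparator: ArmResult
    incremental: IncrementalResult
    wtp: float
    threshold_price: Optional[float]

    @property
    def cost_effective(self) -> bool:
        inc = self.incremental
        if inc.classification == "dominant":
            return True
        if inc.classification in ("dominated", "equivalent"):
            return False
        return inc.delta_effect > 0 and inc.icer is not None and inc.icer <= self.wtp

    def rows(self) -> list[dict]:
        """Base-case results in a tabular per-arm layout."""
        inc = self.incremental
        return [
            {"arm": self.comparator.name, "cost": self.comparator.cost,
             "effect_qald": self.comparator.effect, "icer": None},
            {"arm": self.treatment.name, "cost": self.treatment.cost,
             "effect_qald": self.treatment.effect,
             "icer": inc.icer if inc.classification == "icer_defined" else None},
        ]


def evaluate_base_case(config) -> BaseCaseResult:
    """Evaluate both arms at base values and compare them.

    ``config`` is any object exposing ``treatment_spec()``, ``comparator_spec()``,
    ``horizon_hours`` and ``wtp`` (normally a :class:`ceatree.params_io.ModelConfig`).
    """
    t = evaluate_arm(config.treatment_spec(), config.horizon_hours)
    c = evaluate_arm(config.comparator_spec(), config.horizon_hours)
    inc = incremental(t, c)
    try:
        price = threshold_price(config)
    except ModelError:
        price = None
    return BaseCaseResult(
        treatment=t, comparator=c, incremental=inc, wtp=config.wtp,
        threshold_price=price,
    )
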