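"""Read, validate and derive model parameters for the decision tree.

A model configuration mirrors the three input tables of a single-dose
acute-treatment cost-effectiveness analysis:

* transition probabilities per arm, given either as responder counts
  (``successes``/``failures``) or directly as probabilities — the 2-hour
  probabilities of the PF and FMBS principal states plus the conditional
  time-to-relief splits for the 15/30/45/60/90-minute bins (the 120-minute
  bin and the treatment-ineffectiveness probability are complements, derived
  on load);
* utility values per health state with low/high/SD — only pain-freedom
  utilities and the sustained-pain utility are configured; FMBS utilities are
  derived by multiplying the pain-freedom utility of the same time bin by a
  constant factor (default 0.87) unless explicitly overridden;
* per-dose drug costs with low/high/SD.

The module also moment-matches the probabilistic-sensitivity-analysis
distributions: beta(α, β) for count-based probabilities, beta matched to
(base, SD) for utilities, gamma matched to (base, SD) for costs, with a
point mass wherever the SD is zero or a moment match is infeasible.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .tree import ArmSpec, TimedBranch

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "ResponderCounts",
    "UtilityEntry",
    "CostEntry",
    "DistributionSpec",
    "ProbabilityParam",
    "ArmParams",
    "ModelConfig",
    "conditional_probability",
    "residual_probability",
    "mbs_utility",
    "build_distribution",
    "make_arm_spec",
    "model_config_from_dict",
    "load_model_config",
    "packaged_config_path",
    "load_packaged_config",
    "probabilities_table",
    "utilities_table",
    "costs_table",
    "export_tables",
]

DEFAULT_TIME_BINS = (15, 30, 45, 60, 90, 120)
DEFAULT_MBS_FACTOR = 0.87
_SUM_TOL = 1e-9


class ConfigError(ValueError):
    """A configuration value violates an invariant; the message names the key."""


# ---------------------------------------------------------------------------
# entry types


@dataclass(frozen=True)
class ResponderCounts:
    """Responders (successes) and non-responders (failures) for one endpoint."""

    successes: int
    failures: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.successes < 0 or self.failures < 0:
            raise ConfigError(f"{self.label or 'counts'}: counts must be non-negative")
        if self.total == 0:
            raise ConfigError(f"{self.label or 'counts'}: total count is zero")

    @property
    def total(self) -> int:
        return self.successes + self.failures


@dataclass(frozen=True)
class UtilityEntry:
    """A health-state utility with its deterministic range and PSA spread."""

    base: float
    low: float
    high: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.base <= self.high <= 1.0:
            raise ConfigError(
                f"{self.label or 'utility'}: requires 0 <= low <= base <= high <= 1, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.sd < 0:
            raise ConfigError(f"{self.label or 'utility'}: sd must be non-negative")


@dataclass(frozen=True)
class CostEntry:
    """A per-dose cost (CNY) with its deterministic range and PSA spread."""

    base: float
    low: float
    high: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.base <= self.high:
            raise ConfigError(
                f"{self.label or 'cost'}: requires 0 <= low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.sd < 0:
            raise ConfigError(f"{self.label or 'cost'}: sd must be non-negative")


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one parameter: beta, gamma or point mass.

    ``beta`` uses shape parameters (a, b); ``gamma`` uses shape a and scale b;
    ``point`` puts all mass at a.  Moment-matched families have sampling mean
    equal to the configured base value.
    """

    family: str
    a: float
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "point"):
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma") and (self.a <= 0 or self.b <= 0):
            raise ConfigError(
                f"{self.family} distribution requires positive shape parameters, "
                f"got ({self.a}, {self.b})"
            )

    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        return self.a

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        if size is None:
            return self.a
        return np.full(size, self.a)


@dataclass(frozen=True)
class ProbabilityParam:
    """A transition probability with its source counts (if any) and PSA family."""

    value: float
    distribution: DistributionSpec
    counts: Optional[ResponderCounts] = None
    label: str = ""

    @classmethod
    def from_counts(cls, counts: ResponderCounts, label: str = "") -> "ProbabilityParam":
        label = label or counts.label
        return cls(
            value=conditional_probability(counts),
            distribution=build_distribution(counts),
            counts=counts,
            label=label,
        )

    @classmethod
    def from_value(cls, value: float, label: str = "") -> "ProbabilityParam":
        if not 0.0 <= value <= 1.0:
            raise ConfigError(f"{label or 'probability'}: {value!r} outside [0, 1]")
        return cls(value=value, distribution=DistributionSpec("point", value), label=label)


# ---------------------------------------------------------------------------
# derivation primitives


def conditional_probability(counts: ResponderCounts) -> float:
    """Responder proportion: successes / (successes + failures)."""
    return counts.successes / counts.total


def residual_probability(conditionals: Sequence[float], *, tol: float = _SUM_TOL) -> float:
    """Complement of a set of conditional probabilities (the unlisted last bin)."""
    total = math.fsum(conditionals)
    for p in conditionals:
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"conditional probability {p!r} outside [0, 1]")
    if total > 1.0 + tol:
        raise ConfigError(f"conditional probabilities sum to {total!r} > 1")
    return min(1.0, max(0.0, 1.0 - total))


def mbs_utility(pf_utility: float, factor: float = DEFAULT_MBS_FACTOR) -> float:
    """Utility of freedom from the most bothersome symptom, derived from the
    pain-freedom utility of the same time bin by a constant factor."""
    if not 0.0 <= pf_utility <= 1.0:
        raise ConfigError(f"pain-freedom utility {pf_utility!r} outside [0, 1]")
    if not 0.0 < factor <= 1.0:
        raise ConfigError(f"MBS utility factor {factor!r} outside (0, 1]")
    return pf_utility * factor


def _beta_from_mean_sd(mean: float, sd: float) -> Optional[tuple[float, float]]:
    # method of moments: k = m(1-m)/sd^2 - 1; infeasible when sd^2 >= m(1-m)
    if not 0.0 < mean < 1.0:
        return None
    var = sd * sd
    if var >= mean * (1.0 - mean):
        return None
    k = mean * (1.0 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


def build_distribution(
    entry: Union[ResponderCounts, UtilityEntry, CostEntry]
) -> DistributionSpec:
    """PSA distribution for one parameter: beta(α, β) for counts, moment-matched
    beta for utilities, moment-matched gamma for costs; point mass when the SD
    is zero or a moment match is infeasible (logged)."""
    if isinstance(entry, ResponderCounts):
        if entry.successes == 0 or entry.failures == 0:
            p = conditional_probability(entry)
            logger.warning(
                "%s: degenerate counts (%d, %d); using point mass at %.6g",
                entry.label or "counts", entry.successes, entry.failures, p,
            )
            return DistributionSpec("point", p)
        return DistributionSpec("beta", float(entry.successes), float(entry.failures))
    if isinstance(entry, UtilityEntry):
        if entry.sd == 0:
            return DistributionSpec("point", entry.base)
        shapes = _beta_from_mean_sd(entry.base, entry.sd)
        if shapes is None:
            logger.warning(
                "%s: beta moment match infeasible for (base=%g, sd=%g); "
                "using point mass", entry.label or "utility", entry.base, entry.sd,
            )
            return DistributionSpec("point", entry.base)
        return DistributionSpec("beta", *shapes)
    if isinstance(entry, CostEntry):
        if entry.sd == 0 or entry.base == 0:
            if entry.sd > 0:
                logger.warning(
                    "%s: gamma moment match infeasible for zero base; using point mass",
                    entry.label or "cost",
                )
            return DistributionSpec("point", entry.base)
        shape = (entry.base / entry.sd) ** 2
        scale = entry.sd**2 / entry.base
        return DistributionSpec("gamma", shape, scale)
    raise TypeError(f"cannot build a distribution from {type(entry).__name__}")


# ---------------------------------------------------------------------------
# arm and model containers


@dataclass(frozen=True)
class ArmParams:
    """All configured parameters of one arm, before branch assembly.

    ``pf_bins`` / ``fmbs_bins`` hold the conditional probabilities of the
    listed (non-residual) time bins, keyed by minutes.
    """

    name: str
    dose_cost: CostEntry
    cost_distribution: DistributionSpec
    p_pf: ProbabilityParam
    p_fmbs: ProbabilityParam
    pf_bins: dict[int, ProbabilityParam]
    fmbs_bins: dict[int, ProbabilityParam]

    def __post_init__(self) -> None:
        if self.p_pf.value + self.p_fmbs.value > 1 + _SUM_TOL:
            raise ConfigError(
                f"arm {self.name!r}: pain_freedom_2h + fmbs_2h probabilities sum to "
                f"{self.p_pf.value + self.p_fmbs.value!r} > 1"
            )

    def bin_values(self, state: str) -> list[float]:
        bins = self.pf_bins if state == "pf" else self.fmbs_bins
        return [bins[t].value for t in sorted(bins)]


@dataclass(frozen=True)
class ModelConfig:
    """A fully derived two-arm model configuration."""

    treatment: ArmParams
    comparator: ArmParams
    pf_utilities: dict[int, UtilityEntry]
    ti_utility: UtilityEntry
    horizon_hours: float = 2.0
    wtp: float = 734.45
    mbs_utility_factor: float = DEFAULT_MBS_FACTOR
    time_bins: tuple[int, ...] = DEFAULT_TIME_BINS
    fmbs_utilities: Optional[dict[int, UtilityEntry]] = None
    utility_sampling: str = "independent"
    name: str = "model"

    def __post_init__(self) -> None:
        if self.horizon_hours <= 0:
            raise ConfigError("horizon_hours must be positive")
        if self.wtp < 0:
            raise ConfigError("wtp_per_qald must be non-negative")
        if not 0.0 < self.mbs_utility_factor <= 1.0:
            raise ConfigError("mbs_utility_factor must be in (0, 1]")
        if list(self.time_bins) != sorted(set(self.time_bins)):
            raise ConfigError("time_bins_min must be strictly increasing")
        if self.time_bins[-1] != round(self.horizon_hours * 60):
            raise ConfigError(
                f"last time bin ({self.time_bins[-1]} min) must end at the horizon "
                f"({self.horizon_hours} h)"
            )
        if self.utility_sampling not in ("independent", "shared"):
            raise ConfigError("psa.utility_sampling must be 'independent' or 'shared'")
        if set(self.pf_utilities) != set(self.time_bins):
            raise ConfigError(
                "utilities.pain_freedom must cover exactly the configured time bins"
            )
        for arm in (self.treatment, self.comparator):
            for state, bins in (("pain_freedom_bins", arm.pf_bins),
                                ("fmbs_bins", arm.fmbs_bins)):
                expected = set(self.time_bins[:-1])
                if set(bins) != expected:
                    raise ConfigError(
                        f"arms.{arm.name}.{state}: must list exactly the non-residual "
                        f"bins {sorted(expected)}"
                    )
                resid = residual_probability([bins[t].value for t in sorted(bins)])
                logger.info(
                    "arm %s %s: derived residual %d-min probability %.6f",
                    arm.name, state, self.time_bins[-1], resid,
                )

    # -- derived views ------------------------------------------------------

    def fmbs_utility_value(self, time_min: int) -> float:
        if self.fmbs_utilities is not None:
            return self.fmbs_utilities[time_min].base
        return mbs_utility(self.pf_utilities[time_min].base, self.mbs_utility_factor)

    def _spec(self, arm: ArmParams) -> ArmSpec:
        return make_arm_spec(
            name=arm.name,
            dose_cost=arm.dose_cost.base,
            p_pf=arm.p_pf.value,
            p_fmbs=arm.p_fmbs.value,
            pf_bin_probs=arm.bin_values("pf"),
            fmbs_bin_probs=arm.bin_values("fmbs"),
            pf_utilities={t: u.base for t, u in self.pf_utilities.items()},
            ti_utility=self.ti_utility.base,
            mbs_factor=self.mbs_utility_factor,
            time_bins=self.time_bins,
            fmbs_utilities=(
                {t: u.base for t, u in self.fmbs_utilities.items()}
                if self.fmbs_utilities is not None else None
            ),
        )

    def treatment_spec(self) -> ArmSpec:
        return self._spec(self.treatment)

    def comparator_spec(self) -> ArmSpec:
        return self._spec(self.comparator)

    def arms(self) -> tuple[ArmParams, ArmParams]:
        return (self.treatment, self.comparator)


def make_arm_spec(
    *,
    name: str,
    dose_cost: float,
    p_pf: float,
    p_fmbs: float,
    pf_bin_probs: Sequence[float],
    fmbs_bin_probs: Sequence[float],
    pf_utilities: Mapping[int, float],
    ti_utility: float,
    mbs_factor: float = DEFAULT_MBS_FACTOR,
    time_bins: Sequence[int] = DEFAULT_TIME_BINS,
    fmbs_utilities: Optional[Mapping[int, float]] = None,
) -> ArmSpec:
    """Assemble an evaluable arm from scalar parameter values.

    ``pf_bin_probs`` / ``fmbs_bin_probs`` list the conditional probabilities of
    the non-residual bins in time order; the final bin takes the complement.
    FMBS branch utilities default to ``mbs_factor`` times the pain-freedom
    utility of the same bin.
    """
    n_listed = len(time_bins) - 1
    if len(pf_bin_probs) != n_listed or len(fmbs_bin_probs) != n_listed:
        raise ConfigError(
            f"arm {name!r}: expected {n_listed} non-residual bin probabilities"
        )
    pf_all = list(pf_bin_probs) + [residual_probability(pf_bin_probs)]
    fmbs_all = list(fmbs_bin_probs) + [residual_probability(fmbs_bin_probs)]
    pf_branches = tuple(
        TimedBranch(t, p, pf_utilities[t]) for t, p in zip(time_bins, pf_all)
    )
    fmbs_branches = tuple(
        TimedBranch(
            t, p,
            fmbs_utilities[t] if fmbs_utilities is not None
            else mbs_utility(pf_utilities[t], mbs_factor),
        )
        for t, p in zip(time_bins, fmbs_all)
    )
    return ArmSpec(
        name=name,
        dose_cost=dose_cost,
        p_pf=p_pf,
        p_fmbs=p_fmbs,
        pf_branches=pf_branches,
        fmbs_branches=fmbs_branches,
        ti_utility=ti_utility,
    )


# ---------------------------------------------------------------------------
# config parsing


def _require(mapping: Mapping, key: str, path: str):
    if not isinstance(mapping, Mapping) or key not in mapping:
        raise ConfigError(f"missing required key {path}.{key}")
    return mapping[key]


def _parse_probability(entry, path: str) -> ProbabilityParam:
    if not isinstance(entry, Mapping):
        raise ConfigError(f"{path}: expected a mapping with counts or a probability")
    if "successes" in entry or "failures" in entry:
        counts = ResponderCounts(
            successes=int(_require(entry, "successes", path)),
            failures=int(_require(entry, "failures", path)),
            label=path,
        )
        return ProbabilityParam.from_counts(counts, label=path)
    if "probability" in entry:
        return ProbabilityParam.from_value(float(entry["probability"]), label=path)
    raise ConfigError(f"{path}: give either successes/failures counts or a probability")


def _parse_bins(entry, path: str, listed_bins: Sequence[int]) -> dict[int, ProbabilityParam]:
    if not isinstance(entry, Mapping):
        raise ConfigError(f"{path}: expected a mapping keyed by minutes")
    bins = {int(t): _parse_probability(v, f"{path}.{t}") for t, v in entry.items()}
    if set(bins) != set(listed_bins):
        raise ConfigError(
            f"{path}: must list exactly the non-residual bins {sorted(listed_bins)} "
            f"(the final bin is derived as the complement)"
        )
    try:
        residual_probability([bins[t].value for t in sorted(bins)])
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return bins


def _parse_utility(entry, path: str) -> UtilityEntry:
    return UtilityEntry(
        base=float(_require(entry, "base", path)),
        low=float(_require(entry, "low", path)),
        high=float(_require(entry, "high", path)),
        sd=float(_require(entry, "sd", path)),
        label=path,
    )


def _parse_cost(entry, path: str) -> CostEntry:
    return CostEntry(
        base=float(_require(entry, "base", path)),
        low=float(_require(entry, "low", path)),
        high=float(_require(entry, "high", path)),
        sd=float(_require(entry, "sd", path)),
        label=path,
    )


def _parse_arm(entry, path: str, listed_bins: Sequence[int]) -> ArmParams:
    name = str(_require(entry, "name", path))
    cost = _parse_cost(_require(entry, "dose_cost", path), f"{path}.dose_cost")
    try:
        return ArmParams(
            name=name,
            dose_cost=cost,
            cost_distribution=build_distribution(cost),
            p_pf=_parse_probability(
                _require(entry, "pain_freedom_2h", path), f"{path}.pain_freedom_2h"
            ),
            p_fmbs=_parse_probability(_require(entry, "fmbs_2h", path), f"{path}.fmbs_2h"),
            pf_bins=_parse_bins(
                _require(entry, "pain_freedom_bins", path),
                f"{path}.pain_freedom_bins", listed_bins,
            ),
            fmbs_bins=_parse_bins(
                _require(entry, "fmbs_bins", path), f"{path}.fmbs_bins", listed_bins
            ),
        )
    except ConfigError:
        raise
    except ValueError as exc:  # re-raise with location
        raise ConfigError(f"{path}: {exc}") from exc


def model_config_from_dict(data: Mapping) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a parsed configuration."""
    if not isinstance(data, Mapping):
        raise ConfigError("configuration root must be a mapping")
    time_bins = tuple(int(t) for t in data.get("time_bins_min", DEFAULT_TIME_BINS))
    if len(time_bins) < 2:
        raise ConfigError("time_bins_min needs at least two bins")
    listed = time_bins[:-1]
    arms = _require(data, "arms", "config")
    treatment = _parse_arm(_require(arms, "treatment", "arms"), "arms.treatment", listed)
    comparator = _parse_arm(_require(arms, "comparator", "arms"), "arms.comparator", listed)
    utilities = _require(data, "utilities", "config")
    pf_raw = _require(utilities, "pain_freedom", "utilities")
    pf_utilities = {
        int(t): _parse_utility(v, f"utilities.pain_freedom.{t}")
        for t, v in pf_raw.items()
    }
    ti_utility = _parse_utility(
        _require(utilities, "sustained_pain", "utilities"), "utilities.sustained_pain"
    )
    fmbs_utilities = None
    if "fmbs" in utilities:
        fmbs_utilities = {
            int(t): _parse_utility(v, f"utilities.fmbs.{t}")
            for t, v in utilities["fmbs"].items()
        }
        if set(fmbs_utilities) != set(time_bins):
            raise ConfigError("utilities.fmbs must cover exactly the configured time bins")
    psa = data.get("psa", {}) or {}
    return ModelConfig(
        treatment=treatment,
        comparator=comparator,
        pf_utilities=pf_utilities,
        ti_utility=ti_utility,
        horizon_hours=float(data.get("horizon_hours", 2.0)),
        wtp=float(data.get("wtp_per_qald", 734.45)),
        mbs_utility_factor=float(data.get("mbs_utility_factor", DEFAULT_MBS_FACTOR)),
        time_bins=time_bins,
        fmbs_utilities=fmbs_utilities,
        utility_sampling=str(psa.get("utility_sampling", "independent")),
        name=str(data.get("name", "model")),
    )


def load_model_config(path: Union[str, Path]) -> ModelConfig:
    """Load a YAML model configuration from disk and derive all parameters."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with path.open("r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return model_config_from_dict(data)


def packaged_config_path(name: str = "rimegepant_china") -> Path:
    """Path to a configuration shipped with the package."""
    ref = resources.files("ceatree").joinpath(f"data/{name}.yaml")
    with resources.as_file(ref) as p:
        return Path(p)


def load_packaged_config(name: str = "rimegepant_china") -> ModelConfig:
    """Load a packaged configuration (default: single-dose rimegepant 75 mg vs
    placebo for acute migraine in China over a 2-hour horizon)."""
    return load_model_config(packaged_config_path(name))


# ---------------------------------------------------------------------------
# tabular import/export (CSV mirrors of the three input tables)


def probabilities_table(config: ModelConfig) -> pd.DataFrame:
    """Transition probabilities in the input-table layout: one row per endpoint,
    base value plus beta shape columns per arm."""
    rows = []

    def _row(variable: str, t_param: ProbabilityParam, c_param: ProbabilityParam):
        rows.append({
            "input_variable": variable,
            "treatment_base": t_param.value,
            "treatment_alpha": t_param.counts.successes if t_param.counts else None,
            "treatment_beta": t_param.counts.failures if t_param.counts else None,
            "comparator_base": c_param.value,
            "comparator_alpha": c_param.counts.successes if c_param.counts else None,
            "comparator_beta": c_param.counts.failures if c_param.counts else None,
        })

    t, c = config.treatment, config.comparator
    _row("pain_freedom_2h", t.p_pf, c.p_pf)
    _row("fmbs_2h", t.p_fmbs, c.p_fmbs)
    for tm in config.time_bins[:-1]:
        _row(f"pain_freedom_{tm}min", t.pf_bins[tm], c.pf_bins[tm])
    for tm in config.time_bins[:-1]:
        _row(f"fmbs_{tm}min", t.fmbs_bins[tm], c.fmbs_bins[tm])
    return pd.DataFrame(rows)


def utilities_table(config: ModelConfig) -> pd.DataFrame:
    rows = [
        {"health_state": f"pain_freedom_{t}min", "base": u.base, "low": u.low,
         "high": u.high, "sd": u.sd}
        for t, u in sorted(config.pf_utilities.items())
    ]
    u = config.ti_utility
    rows.append({"health_state": "sustained_pain_2h", "base": u.base, "low": u.low,
                 "high": u.high, "sd": u.sd})
    return pd.DataFrame(rows)


def costs_table(config: ModelConfig) -> pd.DataFrame:
    rows = []
    for arm in config.arms():
        c = arm.dose_cost
        rows.append({"arm": arm.name, "base": c.base, "low": c.low, "high": c.high,
                     "sd": c.sd})
    return pd.DataFrame(rows)


def export_tables(config: ModelConfig, directory: Union[str, Path]) -> dict[str, Path]:
    """Write the three parameter tables as CSV files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for stem, frame in (
        ("probabilities", probabilities_table(config)),
        ("utilities", utilities_table(config)),
        ("costs", costs_table(config)),
    ):
        path = directory / f"{stem}.csv"
        frame.to_csv(path, index=False)
        out[stem] = path
    return out
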