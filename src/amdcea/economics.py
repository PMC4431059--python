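"""Decision metrics and the one-way sensitivity-analysis scenario driver.

Incremental values are intervention minus comparator (immediate minus
delayed treatment).  The incremental cost-effectiveness ratio (ICER) is
reported with its cost-effectiveness-plane quadrant: a ratio in the
north-east quadrant, "dominant" when the intervention is cheaper and more
effective, "dominated" when dearer and less effective, and a flagged
ratio in the south-west quadrant (cheaper but less effective), where a
*larger* ICER favours the intervention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import InvalidParameterError, ModelParameters, UtilityTable
from .simulation import ArmResult, StrategyConfig, run_arm

__all__ = [
    "ICERResult",
    "icer",
    "net_monetary_benefit",
    "IncrementalResult",
    "incremental",
    "ScenarioSpec",
    "run_scenarios",
]


@dataclass(frozen=True)
class ICERResult:
    """ICER value (GBP per QALY) plus its quadrant label.

    ``label`` is one of ``ratio``, ``dominant``, ``dominated``,
    ``southwest`` or ``undefined``; ``value`` is None except for ``ratio``
    and ``southwest``.
    """

    value: float | None
    label: str

    def __str__(self) -> str:
        return self.label if self.value is None else f"{self.value:.2f} ({self.label})"


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """Quadrant-aware incremental cost-effectiveness ratio."""
    if delta_qaly == 0:
        return ICERResult(None, "undefined")
    if delta_qaly > 0:
        if delta_cost <= 0:
            return ICERResult(None, "dominant")
        return ICERResult(delta_cost / delta_qaly, "ratio")
    if delta_cost >= 0:
        return ICERResult(None, "dominated")
    return ICERResult(delta_cost / delta_qaly, "southwest")


def net_monetary_benefit(delta_cost: float, delta_qaly: float, lam: float) -> float:
    """NMB = lambda * dE - dC at willingness-to-pay ``lam`` (GBP per QALY)."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return lam * delta_qaly - delta_cost


@dataclass(frozen=True)
class IncrementalResult:
    comparator: ArmResult
    intervention: ArmResult

    @property
    def delta_cost(self) -> float:
        return self.intervention.mean_cost - self.comparator.mean_cost

    @property
    def delta_qaly(self) -> float:
        return self.intervention.mean_qaly - self.comparator.mean_qaly

    @property
    def icer(self) -> ICERResult:
        return icer(self.delta_cost, self.delta_qaly)

    def as_row(self) -> dict:
        res = self.icer
        return {
            "comparator_cost": self.comparator.mean_cost,
            "intervention_cost": self.intervention.mean_cost,
            "incremental_cost": self.delta_cost,
            "comparator_qaly": self.comparator.mean_qaly,
            "intervention_qaly": self.intervention.mean_qaly,
            "incremental_qaly": self.delta_qaly,
            "icer": res.value if res.value is not None else math.nan,
            "icer_label": res.label,
        }


def incremental(
    params: ModelParameters,
    n_patients: int,
    seed,
    horizon_months: int | None = None,
    fixed_age: float | None = None,
) -> IncrementalResult:
    """Run both arms on common random numbers and return the increments."""
    horizon = horizon_months if horizon_months is not None else params.horizon_months
    comp = run_arm(
        StrategyConfig("delayed", horizon_months=horizon), params, n_patients, seed, fixed_age
    )
    inter = run_arm(
        StrategyConfig("immediate", horizon_months=horizon), params, n_patients, seed, fixed_age
    )
    return IncrementalResult(comp, inter)


_ALLOWED_OVERRIDES = frozenset({"utilities", "drug_only", "horizon_months", "fixed_age"})


@dataclass(frozen=True)
class ScenarioSpec:
    """One-way sensitivity scenario: a named set of parameter overrides.

    Allowed override keys: ``utilities`` (an alternative
    :class:`~amdcea.params.UtilityTable` or ``{"means": [...], "sds": [...]}``),
    ``drug_only`` (bool: strip assessment and monitoring costs),
    ``horizon_months`` (int), ``fixed_age`` (years).
    """

    name: str
    overrides: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - _ALLOWED_OVERRIDES
        if unknown:
            raise InvalidParameterError(
                f"scenario {self.name!r}: unknown override keys {sorted(unknown)}"
            )

    def apply(
        self, params: ModelParameters
    ) -> tuple[ModelParameters, int | None, float | None]:
        horizon = self.overrides.get("horizon_months")
        fixed_age = self.overrides.get("fixed_age")
        if "utilities" in self.overrides:
            util = self.overrides["utilities"]
            if not isinstance(util, UtilityTable):
                util = UtilityTable(np.asarray(util["means"]), np.asarray(util["sds"]))
            params = params.with_overrides(utilities=util)
        if self.overrides.get("drug_only"):
            params = params.with_overrides(
                costs=_replace_costs(params, drug_only=True)
            )
        return params, horizon, fixed_age


def _replace_costs(params: ModelParameters, **kwargs):
    from dataclasses import replace

    return replace(params.costs, **kwargs)


def run_scenarios(
    scenarios: Sequence[ScenarioSpec],
    params: ModelParameters,
    n_patients: int,
    seed,
) -> pd.DataFrame:
    """Run the base case plus each scenario on common random numbers.

    Returns one row per scenario with per-arm costs and QALYs, increments,
    the ICER, and the percent change in ICER vs. the base case (rounded to
    the nearest integer, as conventionally reported).
    """
    rows = []
    base = incremental(params, n_patients, seed)
    base_icer = base.icer
    rows.append({"scenario": "base case", **base.as_row(), "icer_pct_change": 0})
    for spec in scenarios:
        sc_params, horizon, fixed_age = spec.apply(params)
        res = incremental(sc_params, n_patients, seed, horizon_months=horizon, fixed_age=fixed_age)
        row = {"scenario": spec.name, **res.as_row()}
        if base_icer.value and res.icer.value is not None:
            row["icer_pct_change"] = round(
                100.0 * (res.icer.value - base_icer.value) / base_icer.value
            )
        else:
            row["icer_pct_change"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
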