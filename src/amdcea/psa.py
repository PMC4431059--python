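"""Probabilistic sensitivity analysis: sample parameter sets, run both
arms per draw, and summarise the cost-effectiveness plane and
acceptability curve.

Parameter uncertainty is propagated with the standard distribution
choices for economic models: beta for utilities (moment-matched to the
published mean/SD), gamma for unit costs (SD taken as 10% of the mean,
since cost SDs were not published), and Dirichlet for transition-matrix
rows (pseudo-counts ``row * effective_n``; the spread is not identifiable
from the published tables, so ``effective_n`` is explicit configuration).
Draws are independent across parameters.  Within an iteration both arms
run on common random numbers, so the incremental pair (dC, dE) reflects
parameter uncertainty rather than patient-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import (
    DistributionSpec,
    ModelParameters,
    TransitionMatrix,
    UtilityTable,
    beta_params_from_moments,
    dirichlet_alpha_from_row,
    gamma_params_from_moments,
)
from .simulation import StrategyConfig, run_arm

__all__ = [
    "ParameterDistributions",
    "build_distributions",
    "sample_parameter_set",
    "PSAResult",
    "run_psa",
    "ceac",
    "ce_plane",
    "plot_ce_plane",
    "plot_ceac",
]

DEFAULT_LAMBDA_GRID = np.arange(0.0, 50_000.0 + 1, 500.0)


@dataclass(frozen=True)
class ParameterDistributions:
    """Fitted sampling distributions for every uncertain parameter."""

    utilities: list[DistributionSpec]
    drug_cost: DistributionSpec
    assessment_cost: DistributionSpec
    monitoring_cost: DistributionSpec
    loading_row: DistributionSpec
    monthly_rows: list[DistributionSpec]


def _moment_spec(family: str, mean: float, sd: float) -> DistributionSpec:
    """Beta/gamma spec from moments; a zero sd collapses to a point mass."""
    if sd == 0.0:
        return DistributionSpec("point", {"value": mean})
    if family == "beta":
        return beta_params_from_moments(mean, sd)
    return gamma_params_from_moments(mean, sd)


def _row_spec(row: np.ndarray, effective_n: float | None) -> DistributionSpec:
    if effective_n is None:
        return DistributionSpec("point", {"value": np.asarray(row, dtype=float)})
    return dirichlet_alpha_from_row(row, effective_n)


def build_distributions(
    params: ModelParameters,
    effective_n: float | None = None,
    cost_sd_fraction: float | None = None,
) -> ParameterDistributions:
    """Fit PSA distributions to the base-case parameters.

    ``effective_n`` defaults to the configured Dirichlet pseudo-count;
    pass ``None`` explicitly via ``effective_n=0`` semantics is not
    supported — use ``cost_sd_fraction=0`` and utility sds of 0 for a
    degenerate (point-mass) PSA, or ``effective_n=float("inf")`` which is
    treated as a point mass on the transition rows.
    """
    if effective_n is None:
        effective_n = params.dirichlet_effective_n
    if cost_sd_fraction is None:
        cost_sd_fraction = params.cost_sd_fraction
    row_n = None if np.isinf(effective_n) else effective_n
    c = params.costs
    return ParameterDistributions(
        utilities=[
            _moment_spec("beta", m, s)
            for m, s in zip(params.utilities.means, params.utilities.sds)
        ],
        drug_cost=_moment_spec("gamma", c.drug_per_injection, c.drug_per_injection * cost_sd_fraction),
        assessment_cost=_moment_spec("gamma", c.assessment, c.assessment * cost_sd_fraction),
        monitoring_cost=_moment_spec("gamma", c.monitoring, c.monitoring * cost_sd_fraction),
        loading_row=_row_spec(params.loading_row, row_n),
        monthly_rows=[_row_spec(row, row_n) for row in params.monthly.probs],
    )


def sample_parameter_set(
    dists: ParameterDistributions,
    params: ModelParameters,
    rng: np.random.Generator,
) -> ModelParameters:
    """Draw one parameter set; sampled utilities keep death at 0 and the
    base-case ordering is not enforced (sampled sets may cross)."""
    means = np.array([spec.sample(rng) for spec in dists.utilities])
    utilities = UtilityTable(means, params.utilities.sds)
    costs = replace(
        params.costs,
        drug_per_injection=float(dists.drug_cost.sample(rng)),
        assessment=float(dists.assessment_cost.sample(rng)),
        monitoring=float(dists.monitoring_cost.sample(rng)),
    )
    loading = np.asarray(dists.loading_row.sample(rng), dtype=float)
    monthly = np.vstack([np.asarray(spec.sample(rng), dtype=float) for spec in dists.monthly_rows])
    return params.with_overrides(
        utilities=utilities,
        costs=costs,
        loading_row=loading,
        monthly=TransitionMatrix("monthly", monthly),
    )


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration arm outcomes and increments from the PSA."""

    draws: pd.DataFrame
    n_iterations: int
    n_patients_per_iteration: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.draws) != self.n_iterations:
            raise ValueError("draw count does not match iteration count")
        vals = self.draws[["delta_cost", "delta_qaly"]].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite incremental values in PSA result")

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws["delta_cost"].to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.draws["delta_qaly"].to_numpy()

    def central_icer(self) -> float:
        """Ratio of means over iterations (mean dC / mean dE)."""
        return float(self.delta_cost.mean() / self.delta_qaly.mean())


def run_psa(
    params: ModelParameters,
    n_iterations: int,
    seed: int,
    n_patients_per_iteration: int = 1,
    horizon_months: int | None = None,
    effective_n: float | None = None,
    cost_sd_fraction: float | None = None,
) -> PSAResult:
    """Monte Carlo PSA: one parameter draw per iteration, both arms run on
    common random numbers per draw.

    The default of one patient path per iteration reads the published
    "10 000 Monte Carlo simulations" most literally (parameter and patient
    sampling conflated); ``n_patients_per_iteration`` supports the nested
    N_outer x N_inner design instead.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    dists = build_distributions(params, effective_n, cost_sd_fraction)
    horizon = horizon_months if horizon_months is not None else params.horizon_months
    comp_strategy = StrategyConfig("delayed", horizon_months=horizon)
    int_strategy = StrategyConfig("immediate", horizon_months=horizon)
    rows = []
    for it in range(n_iterations):
        param_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, it]))
        drawn = sample_parameter_set(dists, params, param_rng)
        patient_seed = (int(seed), 2, it)
        comp = run_arm(comp_strategy, drawn, n_patients_per_iteration, patient_seed)
        inter = run_arm(int_strategy, drawn, n_patients_per_iteration, patient_seed)
        rows.append(
            {
                "iteration": it,
                "comparator_cost": comp.mean_cost,
                "comparator_qaly": comp.mean_qaly,
                "intervention_cost": inter.mean_cost,
                "intervention_qaly": inter.mean_qaly,
                "delta_cost": inter.mean_cost - comp.mean_cost,
                "delta_qaly": inter.mean_qaly - comp.mean_qaly,
            }
        )
    return PSAResult(
        draws=pd.DataFrame(rows),
        n_iterations=n_iterations,
        n_patients_per_iteration=n_patients_per_iteration,
        seed=int(seed),
    )


def ceac(result: PSAResult, lambda_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay lambda, the probability that immediate
    treatment is cost-effective = the fraction of iterations with positive
    net monetary benefit (lambda * dE - dC > 0).
    """
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    dc = result.delta_cost[:, None]
    de = result.delta_qaly[:, None]
    prob = (lambda_grid[None, :] * de - dc > 0).mean(axis=0)
    return pd.DataFrame({"lambda": lambda_grid, "probability": prob})


def ce_plane(result: PSAResult) -> pd.DataFrame:
    """Incremental (cost, QALY) pairs for the cost-effectiveness plane."""
    return result.draws[["iteration", "delta_cost", "delta_qaly"]].copy()


def plot_ce_plane(result: PSAResult, threshold: float = 20_000.0, ax=None):
    """Scatter of (dE, dC) pairs with the willingness-to-pay threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.delta_qaly, result.delta_cost, s=4, alpha=0.4)
    xs = np.linspace(*ax.get_xlim(), 10)
    ax.plot(xs, threshold * xs, "k--", lw=1, label=f"£{threshold:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (GBP)")
    ax.legend()
    return ax


def plot_ceac(curve: pd.DataFrame, ax=None):
    """Acceptability curves of immediate treatment and its complement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["lambda"], curve["probability"], label="immediate treatment")
    ax.plot(curve["lambda"], 1.0 - curve["probability"], label="delayed treatment")
    ax.set_xlabel("Willingness to pay (GBP per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
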