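"""Patient-level Markov engine for the immediate vs. delayed treatment arms.

Model structure: a single 3-month loading cycle followed by monthly cycles
to the horizon (24 months by default, no discounting).  In the immediate
arm every patient starts in the best visual-acuity band, receives three
loading injections over the loading cycle, then pro-re-nata (PRN)
injections monthly.  In the delayed arm the patient stays untreated in the
best band until vision drops below 6/12 (monthly hazard derived from an
exponential time-to-event stand-in), re-enters in a worse band drawn from
the observed re-entry distribution, and only then starts loading + PRN.

Conventions (fixed and covered by tests):

* mortality is checked at the start of every cycle, before the VA
  transition; a patient who dies accrues nothing in that cycle
  (no half-cycle correction);
* the state at cycle start accrues utility for the whole cycle
  (``utility * cycle_length / 12`` QALYs);
* each injection costs drug + assessment; each non-injection monthly
  visit costs monitoring; untreated delayed-arm months cost nothing;
* per-cycle random draws occur in a fixed order (drop, death, injection,
  transition) so that scenario runs sharing a seed share trajectories.

``cohort_expectation`` is the deterministic oracle: it propagates the
state-occupancy vector through the same cycle structure and integrates
over the age/gender mixture, and must agree with the Monte Carlo
``run_arm`` within sampling error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .params import ModelParameters, VAState, N_BANDS

__all__ = [
    "MortalityModel",
    "annual_to_monthly",
    "StrategyConfig",
    "CycleRecord",
    "PatientTrajectory",
    "ArmResult",
    "simulate_patient",
    "run_arm",
    "cohort_expectation",
]


def annual_to_monthly(annual_q: float) -> float:
    """Convert an annual death probability to monthly: 1 - (1 - q)^(1/12)."""
    if not 0.0 <= annual_q <= 1.0:
        raise ValueError("annual probability must lie in [0, 1]")
    return 1.0 - (1.0 - annual_q) ** (1.0 / 12.0)


class MortalityModel:
    """Gender-specific annual death probabilities by age.

    Backed by a table of q(age) at pivot ages; log-linearly interpolated
    in between and clamped (with a warning) outside the tabulated range.
    """

    def __init__(self, male: dict[int, float], female: dict[int, float]):
        self._tables = {}
        for gender, table in (("male", male), ("female", female)):
            ages = np.array(sorted(table), dtype=float)
            q = np.array([table[int(a)] for a in ages], dtype=float)
            with np.errstate(divide="ignore"):
                logq = np.log(np.maximum(q, 1e-300))
            self._tables[gender] = (ages, q, logq)

    @classmethod
    def from_params(cls, params: ModelParameters) -> "MortalityModel":
        return cls(params.mortality_male, params.mortality_female)

    def annual_death_probability(self, age: float, gender: str) -> float:
        ages, q, logq = self._tables[gender]
        if age < ages[0] or age > ages[-1]:
            warnings.warn(
                "age outside mortality table range; clamping to boundary",
                stacklevel=2,
            )
            age = min(max(age, ages[0]), ages[-1])
        if np.any(q == 0.0):
            # degenerate (e.g. zero-mortality test tables): linear interpolation
            return float(np.interp(age, ages, q))
        return float(np.exp(np.interp(age, ages, logq)))

    def monthly_death_probability(self, age: float, gender: str) -> float:
        return annual_to_monthly(self.annual_death_probability(age, gender))


@dataclass(frozen=True)
class StrategyConfig:
    """Arm rules: ``immediate`` or ``delayed``.

    ``loading_months`` is 3 in the base case; 0 skips the loading cycle
    (used for structural tests).  The horizon includes the delay period of
    the delayed arm.
    """

    arm: str
    horizon_months: int = 24
    loading_months: int = 3
    delay_median_months: float | None = None  # delayed arm; None -> params default

    def __post_init__(self) -> None:
        if self.arm not in ("immediate", "delayed"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.horizon_months < self.loading_months:
            raise ValueError("horizon must be >= loading length")
        if self.loading_months not in (0, 3):
            raise ValueError("loading cycle is 3 months (or 0 to disable)")


@dataclass(frozen=True)
class CycleRecord:
    month: int
    length_months: int
    state: int  # VAState value; 6 = death
    alive: bool
    utility: float
    cost: float
    injections: int


@dataclass
class PatientTrajectory:
    age0: float
    gender: str
    arm: str
    cycles: list[CycleRecord] = field(default_factory=list)
    delay_months: int | None = None

    @property
    def total_qalys(self) -> float:
        return sum(c.utility for c in self.cycles)

    @property
    def total_cost(self) -> float:
        return sum(c.cost for c in self.cycles)

    @property
    def total_injections(self) -> int:
        return sum(c.injections for c in self.cycles)


@dataclass(frozen=True)
class ArmResult:
    arm: str
    n: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    mean_injections: float

    def as_dict(self) -> dict:
        return {
            "arm": self.arm,
            "n": self.n,
            "mean_cost": self.mean_cost,
            "se_cost": self.se_cost,
            "mean_qaly": self.mean_qaly,
            "se_qaly": self.se_qaly,
            "mean_injections": self.mean_injections,
        }


def _delay_hazard(median_months: float) -> float:
    """Monthly drop hazard matching an exponential with the given median."""
    return 1.0 - 2.0 ** (-1.0 / median_months)


def _sample_state(cum_row: np.ndarray, u: float) -> int:
    return int(np.searchsorted(cum_row, u, side="right")) + 1


def simulate_patient(
    strategy: StrategyConfig,
    params: ModelParameters,
    rng: np.random.Generator,
    age: float | None = None,
    gender: str | None = None,
    mortality: MortalityModel | None = None,
) -> PatientTrajectory:
    """Simulate one patient through the chosen arm; deterministic given rng state."""
    if (age is None) != (gender is None):
        raise ValueError("age and gender must be given together")
    if age is None:
        age, gender = params.demographics.sample(rng)
    mort = mortality if mortality is not None else MortalityModel.from_params(params)
    costs = params.costs
    horizon = strategy.horizon_months
    cum_monthly = np.cumsum(params.monthly.probs, axis=1)
    cum_loading = np.cumsum(params.loading_row)
    cum_reentry = np.cumsum(params.reentry)

    traj = PatientTrajectory(age0=age, gender=gender, arm=strategy.arm)
    month = 0
    state = int(VAState.BAND_1)

    if strategy.arm == "delayed":
        median = (
            strategy.delay_median_months
            if strategy.delay_median_months is not None
            else params.delay_median_months
        )
        h = _delay_hazard(median)
        u1 = params.utilities.utility(VAState.BAND_1)
        dropped = False
        while month < horizon:
            if rng.random() < h:
                dropped = True
                break
            pm = mort.monthly_death_probability(age, gender)
            if rng.random() < pm:
                traj.cycles.append(CycleRecord(month, 1, int(VAState.DEATH), False, 0.0, 0.0, 0))
                return traj
            traj.cycles.append(CycleRecord(month, 1, state, True, u1 / 12.0, 0.0, 0))
            month += 1
            age += 1.0 / 12.0
        traj.delay_months = month
        if not dropped or month >= horizon:
            return traj
        state = _sample_state(cum_reentry, rng.random())
        # loading cycle: monthly matrix composed over the cycle length
        load_len = min(strategy.loading_months, horizon - month)
        if load_len > 0:
            p_cycle = 1.0 - (1.0 - mort.monthly_death_probability(age, gender)) ** load_len
            if rng.random() < p_cycle:
                traj.cycles.append(
                    CycleRecord(month, load_len, int(VAState.DEATH), False, 0.0, 0.0, 0)
                )
                return traj
            util = params.utilities.utility(state) * load_len / 12.0
            traj.cycles.append(
                CycleRecord(month, load_len, state, True, util,
                            load_len * costs.injection_cost, load_len)
            )
            cum_power = np.cumsum(params.monthly.power(load_len), axis=1)
            state = _sample_state(cum_power[state - 1], rng.random())
            month += load_len
            age += load_len / 12.0
    else:
        load_len = min(strategy.loading_months, horizon)
        if load_len > 0:
            p_cycle = 1.0 - (1.0 - mort.monthly_death_probability(age, gender)) ** load_len
            if rng.random() < p_cycle:
                traj.cycles.append(
                    CycleRecord(month, load_len, int(VAState.DEATH), False, 0.0, 0.0, 0)
                )
                return traj
            util = params.utilities.utility(state) * load_len / 12.0
            traj.cycles.append(
                CycleRecord(month, load_len, state, True, util,
                            load_len * costs.injection_cost, load_len)
            )
            state = _sample_state(cum_loading, rng.random())
            month += load_len
            age += load_len / 12.0

    # PRN phase: monthly cycles to the horizon
    while month < horizon:
        pm = mort.monthly_death_probability(age, gender)
        if rng.random() < pm:
            traj.cycles.append(CycleRecord(month, 1, int(VAState.DEATH), False, 0.0, 0.0, 0))
            return traj
        inject = rng.random() < costs.prn_injection_rate
        cost = costs.injection_cost if inject else costs.visit_cost
        util = params.utilities.utility(state) / 12.0
        traj.cycles.append(CycleRecord(month, 1, state, True, util, cost, int(inject)))
        state = _sample_state(cum_monthly[state - 1], rng.random())
        month += 1
        age += 1.0 / 12.0
    return traj


def _patient_rng(seed, index: int) -> np.random.Generator:
    entropy = list(seed) if isinstance(seed, (tuple, list)) else [int(seed)]
    return np.random.default_rng(np.random.SeedSequence(entropy + [index]))


def run_arm(
    strategy: StrategyConfig,
    params: ModelParameters,
    n_patients: int,
    seed,
    fixed_age: float | None = None,
) -> ArmResult:
    """Monte Carlo estimate of per-arm mean cost and QALYs over ``n_patients``.

    Patient ``i`` gets an independent substream derived from ``(seed, i)``,
    so both arms (and scenario variants) run on common random numbers when
    given the same seed.  ``fixed_age`` pins every patient's starting age
    (gender mix still sampled), as in the starting-age sensitivity scenario.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    mort = MortalityModel.from_params(params)
    qalys = np.empty(n_patients)
    costs = np.empty(n_patients)
    injections = np.empty(n_patients)
    for i in range(n_patients):
        rng = _patient_rng(seed, i)
        age, gender = params.demographics.sample(rng)
        if fixed_age is not None:
            age = float(fixed_age)
        traj = simulate_patient(strategy, params, rng, age=age, gender=gender, mortality=mort)
        qalys[i] = traj.total_qalys
        costs[i] = traj.total_cost
        injections[i] = traj.total_injections
    ddof = 1 if n_patients > 1 else 0
    return ArmResult(
        arm=strategy.arm,
        n=n_patients,
        mean_cost=float(costs.mean()),
        se_cost=float(costs.std(ddof=ddof) / np.sqrt(n_patients)),
        mean_qaly=float(qalys.mean()),
        se_qaly=float(qalys.std(ddof=ddof) / np.sqrt(n_patients)),
        mean_injections=float(injections.mean()),
    )


# ---------------------------------------------------------------------------
# deterministic cohort expectation (oracle for the microsimulation)


def _expectation_one(
    strategy: StrategyConfig,
    params: ModelParameters,
    mort: MortalityModel,
    age0: float,
    gender: str,
    collect_trace: bool = False,
):
    """Exact expected (qalys, cost, injections) for one starting age/gender."""
    costs = params.costs
    u = params.utilities.means
    horizon = strategy.horizon_months
    M = params.monthly.probs
    exp_visit_cost = (
        costs.prn_injection_rate * costs.injection_cost
        + (1.0 - costs.prn_injection_rate) * costs.visit_cost
    )
    trace: list[float] = []

    def prn_phase(occ: np.ndarray, start_month: int, dead_mass: float):
        """Propagate occupancy (mass-carrying) through monthly cycles."""
        q = c = inj = 0.0
        age = age0 + start_month / 12.0
        m = start_month
        while m < horizon:
            pm = mort.monthly_death_probability(age, gender)
            dead_mass += occ.sum() * pm
            occ = occ * (1.0 - pm)
            q += occ @ u / 12.0
            c += occ.sum() * exp_visit_cost
            inj += occ.sum() * costs.prn_injection_rate
            occ = occ @ M
            if collect_trace:
                trace.append(occ.sum() + dead_mass)
            age += 1.0 / 12.0
            m += 1
        return q, c, inj, dead_mass

    def loading_then_prn(entry: np.ndarray, start_month: int, loading_row: np.ndarray | None):
        """Loading cycle (if any) from an entry distribution, then PRN."""
        load_len = min(strategy.loading_months, horizon - start_month)
        if load_len == 0:
            return prn_phase(entry, start_month, dead_mass=1.0 - entry.sum())
        p_cycle = 1.0 - (
            1.0 - mort.monthly_death_probability(age0 + start_month / 12.0, gender)
        ) ** load_len
        surv = entry.sum() * (1.0 - p_cycle)
        q = (entry @ u) * (1.0 - p_cycle) * load_len / 12.0
        c = surv * load_len * costs.injection_cost
        inj = surv * load_len
        if loading_row is not None:
            occ = entry.sum() * (1.0 - p_cycle) * loading_row
        else:
            occ = (entry * (1.0 - p_cycle)) @ np.linalg.matrix_power(M, load_len)
        dead_mass = 1.0 - occ.sum()
        if collect_trace:
            trace.append(occ.sum() + dead_mass)
        q2, c2, inj2, _ = prn_phase(occ, start_month + load_len, dead_mass)
        return q + q2, c + c2, inj + inj2, None

    start = np.zeros(N_BANDS)
    start[0] = 1.0

    if strategy.arm == "immediate":
        row = params.loading_row if strategy.loading_months > 0 else None
        q, c, inj, _ = loading_then_prn(start, 0, row)
        return (q, c, inj, trace) if collect_trace else (q, c, inj)

    median = (
        strategy.delay_median_months
        if strategy.delay_median_months is not None
        else params.delay_median_months
    )
    h = _delay_hazard(median)
    u1 = params.utilities.utility(VAState.BAND_1)
    q = c = inj = 0.0
    w = 1.0  # P(alive and still untreated at start of month m)
    for m in range(horizon):
        # drop branch: enter loading this month
        vq, vc, vinj, _ = loading_then_prn(params.reentry.copy(), m, None)
        q += w * h * vq
        c += w * h * vc
        inj += w * h * vinj
        # untreated branch: survive the month in the best band
        w *= 1.0 - h
        pm = mort.monthly_death_probability(age0 + m / 12.0, gender)
        q += w * (1.0 - pm) * u1 / 12.0
        w *= 1.0 - pm
    return q, c, inj


def cohort_expectation(
    strategy: StrategyConfig,
    params: ModelParameters,
    fixed_age: float | None = None,
    age_step: float = 0.25,
) -> dict:
    """Deterministic expectation of mean cost/QALYs/injections for an arm.

    Integrates the single-patient expectation over the gender mixture and
    the truncated-normal age distributions (discretised at ``age_step``
    years); with ``fixed_age`` only the gender mixture is integrated.
    """
    mort = MortalityModel.from_params(params)
    demo = params.demographics
    tot = np.zeros(3)
    for gender, gp in (("male", demo.male_proportion), ("female", 1.0 - demo.male_proportion)):
        if gp == 0.0:
            continue
        if fixed_age is not None:
            vals = np.array(_expectation_one(strategy, params, mort, fixed_age, gender))
        else:
            grid, wts = demo.age_grid(gender, step=age_step)
            vals = np.zeros(3)
            for a, wt in zip(grid, wts):
                vals += wt * np.array(_expectation_one(strategy, params, mort, a, gender))
        tot += gp * vals
    return {"mean_qaly": float(tot[0]), "mean_cost": float(tot[1]), "mean_injections": float(tot[2])}


def occupancy_conservation_trace(
    params: ModelParameters, age: float = 78.8, gender: str = "male", horizon: int = 24
) -> np.ndarray:
    """Per-cycle total probability mass (alive occupancy + cumulative death).

    Exposed for conservation checks: every entry must equal 1.
    """
    mort = MortalityModel.from_params(params)
    strategy = StrategyConfig("immediate", horizon_months=horizon)
    _, _, _, trace = _expectation_one(strategy, params, mort, age, gender, collect_trace=True)
    return np.asarray(trace)
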