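"""Base-case model parameters and the distributions used for probabilistic
sensitivity analysis.

The model describes the better-seeing eye of a patient with neovascular
age-related macular degeneration (nAMD) moving between five visual-acuity
bands (6/6 to >6/12 down to <3/60) plus an absorbing death state.  This
module houses the parameter containers (transition matrices, utilities,
unit costs, demographics), the YAML loader with validation, and the
moment-matching constructors for the beta / gamma / Dirichlet
distributions that drive probabilistic sensitivity analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "VAState",
    "InvalidParameterError",
    "TransitionMatrix",
    "UtilityTable",
    "CostSchedule",
    "Demographics",
    "DistributionSpec",
    "ModelParameters",
    "renormalize_row",
    "beta_params_from_moments",
    "gamma_params_from_moments",
    "dirichlet_alpha_from_row",
    "load_parameters",
]

N_BANDS = 5

#: pseudo-count floor for structurally-zero Dirichlet entries
DIRICHLET_FLOOR = 1e-6


class InvalidParameterError(ValueError):
    """A parameter failed validation against its documented invariants."""


class VAState(enum.IntEnum):
    """Visual-acuity health states, ordered by declining acuity.

    Bands 1-5 carry utility; ``DEATH`` is absorbing and handled by the
    mortality model rather than the transition matrices.
    """

    BAND_1 = 1  # 6/6 to >6/12
    BAND_2 = 2  # 6/12 to 6/24
    BAND_3 = 3  # 6/24 to 6/60
    BAND_4 = 4  # 6/60 to 3/60
    BAND_5 = 5  # <3/60
    DEATH = 6

    @property
    def label(self) -> str:
        return _STATE_LABELS[self]


_STATE_LABELS = {
    VAState.BAND_1: "6/6 to >6/12",
    VAState.BAND_2: "6/12 to 6/24",
    VAState.BAND_3: "6/24 to 6/60",
    VAState.BAND_4: "6/60 to 3/60",
    VAState.BAND_5: "<3/60",
    VAState.DEATH: "death",
}


def renormalize_row(row: Sequence[float]) -> np.ndarray:
    """Rescale a nonnegative probability row to sum exactly to one.

    Printed transition rows carry rounding error (sums such as 1.0001);
    proportional rescaling preserves the printed ratios.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1:
        raise InvalidParameterError("row must be one-dimensional")
    if np.any(row < 0) or not np.all(np.isfinite(row)):
        raise InvalidParameterError("row entries must be finite and >= 0")
    total = row.sum()
    if total <= 0:
        raise InvalidParameterError("row sums to zero; cannot renormalise")
    if abs(total - 1.0) <= 1e-12:  # already stochastic; keep entries bit-exact
        return row.copy()
    return row / total


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probabilities over the five VA bands.

    ``cycle_kind`` records the cycle the probabilities refer to
    (``"loading_3month"`` for the single 3-month loading cycle,
    ``"monthly"`` for 1-month cycles).  Death is layered on separately.
    """

    cycle_kind: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (N_BANDS, N_BANDS):
            raise InvalidParameterError(
                f"transition matrix must be {N_BANDS}x{N_BANDS}, got {probs.shape}"
            )
        probs = np.vstack([renormalize_row(r) for r in probs])
        if np.any(probs < 0) or np.any(probs > 1):
            raise InvalidParameterError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", probs)
        err = np.abs(probs.sum(axis=1) - 1.0).max()
        if err > 1e-12:
            raise InvalidParameterError(f"row sums deviate from 1 by {err}")

    def row(self, state: int) -> np.ndarray:
        return self.probs[state - 1]

    def power(self, k: int) -> np.ndarray:
        return np.linalg.matrix_power(self.probs, k)


@dataclass(frozen=True)
class UtilityTable:
    """Mean (sd) utility per VA band on the 0-1 scale; death has utility 0."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if means.shape != (N_BANDS,) or sds.shape != (N_BANDS,):
            raise InvalidParameterError("utility table needs 5 means and 5 sds")
        if np.any(means < 0) or np.any(means > 1):
            raise InvalidParameterError("utility means must lie in [0, 1]")
        if np.any(sds < 0):
            raise InvalidParameterError("utility sds must be >= 0")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    def require_monotone(self) -> None:
        if not np.all(np.diff(self.means) < 0):
            raise InvalidParameterError(
                "base-case utilities must decrease strictly with band severity"
            )

    def utility(self, state: int) -> float:
        if state == VAState.DEATH:
            return 0.0
        return float(self.means[state - 1])


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs (GBP, cost year 2012) and the PRN injection frequency.

    Every injection incurs drug + assessment cost; every non-injection
    monthly visit incurs the monitoring cost.  ``drug_only`` is the one-way
    sensitivity scenario that strips visit costs, leaving drug cost only.
    """

    drug_per_injection: float
    assessment: float
    monitoring: float
    prn_injection_rate: float
    drug_only: bool = False

    def __post_init__(self) -> None:
        for name in ("drug_per_injection", "assessment", "monitoring"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.prn_injection_rate <= 1.0:
            raise InvalidParameterError("prn_injection_rate must lie in [0, 1]")

    @property
    def injection_cost(self) -> float:
        if self.drug_only:
            return self.drug_per_injection
        return self.drug_per_injection + self.assessment

    @property
    def visit_cost(self) -> float:
        return 0.0 if self.drug_only else self.monitoring


@dataclass(frozen=True)
class GenderSpec:
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class Demographics:
    """Starting age/gender mixture: truncated-normal ages per gender."""

    male_proportion: float
    male: GenderSpec
    female: GenderSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_proportion <= 1.0:
            raise InvalidParameterError("male_proportion must lie in [0, 1]")
        for spec in (self.male, self.female):
            if not (spec.min < spec.mean < spec.max) or spec.sd <= 0:
                raise InvalidParameterError("age distribution parameters invalid")

    def spec(self, gender: str) -> GenderSpec:
        return self.male if gender == "male" else self.female

    def sample(self, rng: np.random.Generator) -> tuple[float, str]:
        """Draw one (age, gender) pair."""
        gender = "male" if rng.random() < self.male_proportion else "female"
        spec = self.spec(gender)
        # simple rejection sampling: truncation bounds are >3 sd out, so
        # the acceptance rate is essentially 1
        while True:
            age = rng.normal(spec.mean, spec.sd)
            if spec.min <= age <= spec.max:
                return age, gender

    def age_grid(self, gender: str, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
        """Discretised age distribution (grid, weights) for the expectation oracle."""
        from scipy.stats import truncnorm

        spec = self.spec(gender)
        a = (spec.min - spec.mean) / spec.sd
        b = (spec.max - spec.mean) / spec.sd
        grid = np.arange(spec.min, spec.max + step / 2, step)
        w = truncnorm.pdf(grid, a, b, loc=spec.mean, scale=spec.sd)
        return grid, w / w.sum()


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one model parameter.

    ``family`` is ``"beta"`` (params ``alpha``, ``beta``), ``"gamma"``
    (params ``shape``, ``scale``), ``"dirichlet"`` (param ``alpha`` vector),
    or ``"point"`` (param ``value``; degenerate, used when sd == 0).
    """

    family: str
    params: Mapping[str, object]

    def sample(self, rng: np.random.Generator):
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"])
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"])
        if self.family == "dirichlet":
            return rng.dirichlet(np.asarray(self.params["alpha"], dtype=float))
        if self.family == "point":
            value = self.params["value"]
            return np.array(value, dtype=float) if np.ndim(value) else float(value)
        raise InvalidParameterError(f"unknown distribution family {self.family!r}")

    def mean(self):
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        if self.family == "dirichlet":
            alpha = np.asarray(self.params["alpha"], dtype=float)
            return alpha / alpha.sum()
        if self.family == "point":
            return self.params["value"]
        raise InvalidParameterError(f"unknown distribution family {self.family!r}")


def beta_params_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Fit a beta distribution to a (mean, sd) pair by the method of moments.

    With ``nu = mean (1 - mean) / sd^2 - 1``, the fitted parameters are
    ``alpha = mean nu`` and ``beta = (1 - mean) nu``.  Feasibility requires
    ``sd^2 < mean (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise InvalidParameterError("beta mean must lie strictly in (0, 1)")
    if sd <= 0:
        raise InvalidParameterError("beta sd must be > 0")
    bound = mean * (1.0 - mean)
    if sd * sd >= bound:
        raise InvalidParameterError(
            f"infeasible beta moments: need sd^2 < mean*(1-mean) = {bound:.6g}, "
            f"got sd^2 = {sd * sd:.6g}"
        )
    nu = bound / (sd * sd) - 1.0
    return DistributionSpec("beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu})


def gamma_params_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Fit a gamma distribution by moment matching: shape = mean^2/sd^2, scale = sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise InvalidParameterError("gamma moments must be strictly positive")
    return DistributionSpec(
        "gamma", {"shape": (mean / sd) ** 2, "scale": sd * sd / mean}
    )


def dirichlet_alpha_from_row(
    row: Sequence[float], effective_n: float
) -> DistributionSpec:
    """Dirichlet pseudo-counts ``alpha_i = row_i * effective_n`` for a stochastic row.

    Structural zeros are floored at a tiny pseudo-count so the distribution
    stays proper; the Dirichlet mean then equals the input row up to the
    floor.
    """
    row = np.asarray(row, dtype=float)
    if effective_n <= 0:
        raise InvalidParameterError("effective_n must be > 0")
    if abs(row.sum() - 1.0) > 1e-9 or np.any(row < 0):
        raise InvalidParameterError("row must be stochastic (renormalise first)")
    alpha = np.maximum(row * effective_n, DIRICHLET_FLOOR)
    return DistributionSpec("dirichlet", {"alpha": alpha})


@dataclass(frozen=True)
class ModelParameters:
    """Everything the simulation and PSA need, validated at construction."""

    loading_row: np.ndarray
    monthly: TransitionMatrix
    utilities: UtilityTable
    costs: CostSchedule
    demographics: Demographics
    reentry: np.ndarray
    mortality_male: dict[int, float]
    mortality_female: dict[int, float]
    delay_median_months: float = 6.0
    horizon_months: int = 24
    dirichlet_effective_n: float = 100.0
    cost_sd_fraction: float = 0.10
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "loading_row", renormalize_row(self.loading_row))
        object.__setattr__(self, "reentry", renormalize_row(self.reentry))
        if self.delay_median_months <= 0:
            raise InvalidParameterError("delay_median_months must be > 0")
        if self.horizon_months < 3:
            raise InvalidParameterError("horizon must cover the loading cycle")
        for table in (self.mortality_male, self.mortality_female):
            probs = np.array([table[a] for a in sorted(table)])
            if np.any(probs < 0) or np.any(probs > 1):
                raise InvalidParameterError("annual death probabilities must lie in [0, 1]")
            if np.any(np.diff(probs) < 0):
                raise InvalidParameterError(
                    "annual death probabilities must be non-decreasing in age"
                )

    def mortality_table(self, gender: str) -> dict[int, float]:
        return self.mortality_male if gender == "male" else self.mortality_female

    def with_overrides(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


_DEFAULT_PARAMS = Path(__file__).parent / "data" / "base_case.yaml"


def load_parameters(path: str | Path | None = None) -> ModelParameters:
    """Load and validate model parameters from YAML (packaged base case by default)."""
    path = Path(path) if path is not None else _DEFAULT_PARAMS
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - exercised via CLI
        raise InvalidParameterError(f"malformed parameter file {path}: {exc}") from exc
    try:
        trans = raw["transitions"]
        util = raw["utilities"]
        costs = raw["costs"]
        demo = raw["demographics"]
        params = ModelParameters(
            loading_row=np.asarray(trans["loading_3month"], dtype=float),
            monthly=TransitionMatrix("monthly", np.asarray(trans["monthly"], dtype=float)),
            utilities=UtilityTable(np.asarray(util["means"]), np.asarray(util["sds"])),
            costs=CostSchedule(
                drug_per_injection=float(costs["drug_per_injection"]),
                assessment=float(costs["assessment"]),
                monitoring=float(costs["monitoring"]),
                prn_injection_rate=float(costs["prn_injection_rate"]),
                drug_only=bool(costs.get("drug_only", False)),
            ),
            demographics=Demographics(
                male_proportion=float(demo["male_proportion"]),
                male=GenderSpec(**{k: float(v) for k, v in demo["male"].items()}),
                female=GenderSpec(**{k: float(v) for k, v in demo["female"].items()}),
            ),
            reentry=np.asarray(raw["reentry_distribution"], dtype=float),
            mortality_male={int(k): float(v) for k, v in raw["mortality"]["male"].items()},
            mortality_female={int(k): float(v) for k, v in raw["mortality"]["female"].items()},
            delay_median_months=float(raw["delay"]["median_months"]),
            horizon_months=int(raw.get("horizon_months", 24)),
            dirichlet_effective_n=float(raw["psa"]["dirichlet_effective_n"]),
            cost_sd_fraction=float(raw["psa"]["cost_sd_fraction"]),
            meta={
                "version": raw.get("version"),
                "currency": raw.get("currency"),
                "cost_year": raw.get("cost_year"),
                "source_path": str(path),
            },
        )
    except (KeyError, TypeError) as exc:
        raise InvalidParameterError(f"parameter file {path} is missing fields: {exc}") from exc
    # base-case utilities must decline with band severity (sampled PSA sets may cross)
    params.utilities.require_monotone()
    return params
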