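"""Synthetic longitudinal visit records and the estimators that turn such
records into model parameters.

The real parameterisation used clinic-visit records of treated eyes (for
the on-treatment transition matrix and PRN injection frequency) and of
untreated fellow eyes (for the natural-history time to dropping below
6/12).  That dataset is not publicly available, so this module generates
visit tables with the same statistical structure — treated-eye monthly
states Markov with a known matrix, fellow-eye time to first visit below
6/12 following a known survival distribution, injections Bernoulli after
the loading phase — which lets every estimator be validated by parameter
recovery against the generating truth.

Fellow-eye trajectories hold the best band until a drop month sampled
from the configured time-to-threshold distribution (discretised to a
monthly hazard), enter a worse band via the natural-history matrix's
first row conditioned on leaving, and evolve freely by that matrix
afterwards.  Consequently the estimators recover the natural-history
matrix's rows 2-5 and the drop-time distribution, while its first row is
identified only through the survival curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .params import N_BANDS, TransitionMatrix, renormalize_row

__all__ = [
    "EstimationError",
    "GeneratorConfig",
    "SurvivalCurve",
    "VISIT_COLUMNS",
    "ETDRS_BAND_RANGES",
    "letters_to_state",
    "default_natural_history_matrix",
    "generate_cohort",
    "estimate_transition_matrix",
    "estimate_time_to_threshold",
    "estimate_injection_rate",
    "write_visits",
    "read_visits",
]

VISIT_COLUMNS = ["patient_id", "eye_role", "month_index", "va_state", "letters", "injected"]

#: ETDRS letter-score ranges per VA band (inclusive), used only when the
#: generator emits letters; binning at these cut points recovers the band
ETDRS_BAND_RANGES = {1: (70, 95), 2: (55, 69), 3: (35, 54), 4: (20, 34), 5: (0, 19)}


class EstimationError(ValueError):
    """Raised when the visit records cannot support the requested estimate."""


def letters_to_state(letters) -> np.ndarray:
    """Bin ETDRS letter scores to VA bands at the documented cut points."""
    letters = np.asarray(letters)
    cuts = np.array([20, 35, 55, 70])  # lower bounds of bands 4, 3, 2, 1
    return (N_BANDS - np.searchsorted(cuts, letters, side="right")).astype(int)


def default_natural_history_matrix(treated: np.ndarray) -> TransitionMatrix:
    """A documented untreated (fellow-eye) stand-in, strictly worse than treated.

    Untreated eyes deteriorate faster: per row, worsening probabilities are
    doubled and improvement probabilities halved, the diagonal absorbing
    the remainder (monthly probability of leaving the best band is twice
    the treated matrix's).
    """
    treated = np.asarray(treated, dtype=float)
    out = np.zeros_like(treated)
    for i in range(N_BANDS):
        worse = treated[i, i + 1:] * 2.0
        better = treated[i, :i] * 0.5
        diag = 1.0 - worse.sum() - better.sum()
        if diag < 0:
            raise ValueError("cannot construct natural-history matrix: row overflows")
        out[i, :i] = better
        out[i, i] = diag
        out[i, i + 1:] = worse
    return TransitionMatrix("monthly", out)


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and sizes for the synthetic visit generator."""

    n_patients: int
    treated_matrix: np.ndarray
    fellow_matrix: np.ndarray
    months: int = 24
    loading_months: int = 3
    drop_median_months: float = 6.0
    injection_probability: float = 0.24
    include_letters: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.injection_probability <= 1.0:
            raise ValueError("injection_probability must lie in [0, 1]")
        for name in ("treated_matrix", "fellow_matrix"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (N_BANDS, N_BANDS) or np.any(m < 0):
                raise ValueError(f"{name} must be a nonnegative {N_BANDS}x{N_BANDS} matrix")
            if np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{name} rows must sum to 1")


def _markov_step(states: np.ndarray, cum_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    nxt = np.empty_like(states)
    for s in range(1, N_BANDS + 1):
        mask = states == s
        if mask.any():
            nxt[mask] = np.searchsorted(cum_rows[s - 1], u[mask], side="right") + 1
    return nxt


def _sample_letters(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    letters = np.empty(states.shape, dtype=int)
    for band, (lo, hi) in ETDRS_BAND_RANGES.items():
        mask = states == band
        if mask.any():
            letters[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return letters


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a long-format visit table (one treated + one fellow eye per patient).

    Visits run at months 0..``months`` inclusive.  Treated eyes start in
    the best band and evolve by the treated matrix; fellow eyes hold the
    best band until a drop month drawn from the discretised
    time-to-threshold distribution.  Bitwise reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n, months = config.n_patients, config.months
    treated = np.asarray(config.treated_matrix, dtype=float)
    fellow = np.asarray(config.fellow_matrix, dtype=float)
    cum_treated = np.cumsum(treated, axis=1)
    cum_fellow = np.cumsum(fellow, axis=1)

    # treated eye: Markov chain from band 1
    t_states = np.empty((n, months + 1), dtype=int)
    t_states[:, 0] = 1
    for t in range(months):
        t_states[:, t + 1] = _markov_step(t_states[:, t], cum_treated, rng.random(n))
    injected = np.zeros((n, months + 1), dtype=bool)
    injected[:, : config.loading_months] = True
    post = rng.random((n, months + 1 - config.loading_months))
    injected[:, config.loading_months:] = post < config.injection_probability

    # fellow eye: hold band 1 until the sampled drop month, then natural history
    h = 1.0 - 2.0 ** (-1.0 / config.drop_median_months)
    drop_month = rng.geometric(h, size=n)  # first month observed below 6/12
    f_states = np.ones((n, months + 1), dtype=int)
    cond_first = renormalize_row(fellow[0, 1:])  # leaving band 1, conditional
    cum_cond = np.cumsum(cond_first)
    for t in range(1, months + 1):
        at_drop = drop_month == t
        if at_drop.any():
            f_states[at_drop, t] = (
                np.searchsorted(cum_cond, rng.random(int(at_drop.sum())), side="right") + 2
            )
        past = drop_month < t
        if past.any():
            f_states[past, t] = _markov_step(f_states[past, t - 1], cum_fellow, rng.random(n)[past])

    frames = []
    month_idx = np.tile(np.arange(months + 1), n)
    pid = np.repeat(np.arange(n), months + 1)
    for role, states, inj in (("treated", t_states, injected), ("fellow", f_states, None)):
        df = pd.DataFrame(
            {
                "patient_id": pid,
                "eye_role": role,
                "month_index": month_idx,
                "va_state": states.ravel(),
                "letters": (
                    _sample_letters(states, rng).ravel() if config.include_letters else np.nan
                ),
                "injected": inj.ravel() if inj is not None else False,
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["patient_id", "eye_role", "month_index"], ignore_index=True)


def estimate_transition_matrix(
    visits: pd.DataFrame, eye_role: str, cycle_months: int = 1
) -> tuple[TransitionMatrix, np.ndarray]:
    """Row-normalised transition counts over visit pairs spaced ``cycle_months`` apart.

    Returns the estimated matrix together with the raw count matrix.  Rows
    with no observed transitions fall back to the identity row with a
    warning (conservative: the state is held).
    """
    df = visits[visits["eye_role"] == eye_role]
    if df.empty:
        raise EstimationError(f"no visits for eye_role={eye_role!r}")
    df = df.sort_values(["patient_id", "month_index"])
    same_eye = df["patient_id"].values[1:] == df["patient_id"].values[:-1]
    gap = np.diff(df["month_index"].values)
    ok = same_eye & (gap == cycle_months)
    src = df["va_state"].values[:-1][ok]
    dst = df["va_state"].values[1:][ok]
    if len(src) == 0:
        raise EstimationError(
            f"no consecutive visit pairs at spacing {cycle_months} months"
        )
    counts = np.zeros((N_BANDS, N_BANDS))
    np.add.at(counts, (src - 1, dst - 1), 1.0)
    probs = np.empty_like(counts)
    for i in range(N_BANDS):
        total = counts[i].sum()
        if total == 0:
            warnings.warn(
                f"no transitions observed from state {i + 1}; using identity row",
                stacklevel=2,
            )
            probs[i] = np.eye(N_BANDS)[i]
        else:
            probs[i] = counts[i] / total
    kind = "monthly" if cycle_months == 1 else f"{cycle_months}-month"
    return TransitionMatrix(kind, probs), counts


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate of the time to dropping below 6/12."""

    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing within [0, 1]")

    def at(self, t: float) -> float:
        """S(t), right-continuous; S(0) = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
            }
        )


def _fellow_durations(visits: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    fellow = visits[visits["eye_role"] == "fellow"]
    if fellow.empty:
        raise EstimationError("no fellow-eye records")
    durations, events = [], []
    for _, grp in fellow.groupby("patient_id"):
        grp = grp.sort_values("month_index")
        below = grp[grp["va_state"] >= 2]
        if len(below):
            durations.append(below["month_index"].iloc[0])
            events.append(1)
        else:
            durations.append(grp["month_index"].iloc[-1])
            events.append(0)
    return np.asarray(durations, dtype=float), np.asarray(events, dtype=int)


def estimate_time_to_threshold(visits: pd.DataFrame) -> SurvivalCurve:
    """Kaplan-Meier estimate of months from first fellow-eye visit to the
    first visit below 6/12 (band >= 2); eyes never observed below are
    censored at their last visit."""
    durations, events = _fellow_durations(visits)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(times).to_numpy()
    return SurvivalCurve(
        times=times,
        survival=survival,
        n_risk=table["at_risk"].to_numpy(dtype=float),
        n_event=table["observed"].to_numpy(dtype=float),
    )


def estimate_injection_rate(visits: pd.DataFrame, loading_months: int = 3) -> float:
    """Injections per treated-eye post-loading visit-month, in [0, 1]."""
    treated = visits[(visits["eye_role"] == "treated") & (visits["month_index"] >= loading_months)]
    if treated.empty:
        raise EstimationError("no post-loading treated-eye visits")
    return float(treated["injected"].mean())


def write_visits(visits: pd.DataFrame, path: str | Path) -> None:
    visits.to_csv(path, index=False, columns=VISIT_COLUMNS)


def read_visits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise EstimationError(f"visit file missing columns: {sorted(missing)}")
    df["injected"] = df["injected"].astype(bool)
    return df
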