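"""Synthetic elicitation surveys and intervention cohorts.

Two generators mirror the data structures of the minimal-dose training
studies this package analyses:

* :func:`generate_elicitation` — survey responses giving, per respondent and
  per outcome (squat, bench press, deadlift, powerlifting total), the 1RM
  change in kg the respondent considers meaningful over six weeks.  Defaults
  reproduce the published survey summary (n=137; e.g. total 17.5 ± 12.1 kg).
* :func:`generate_cohort` — a two-arm (or k-arm) quasi-randomized training
  cohort with per-athlete pre/post 1RM per lift, body mass, Wilks points,
  strength class and per-session training logs (RPE, next-day soreness,
  AMRAP repetitions).

Elicited responses and change scores are modelled as normal; truncation at
zero (meaningful changes are positive) and exact sample moment matching are
optional.  The distributional shape is an assumption — only means and SDs of
the real survey are published.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .protocols import LIFTS, get_protocol, strength_class, wilks_score

__all__ = [
    "OUTCOMES",
    "ElicitationConfig",
    "GroupConfig",
    "CohortConfig",
    "InterventionDataset",
    "generate_elicitation",
    "generate_cohort",
    "apply_dropout",
]

OUTCOMES = ("SQ", "BP", "DL", "Total")

#: Published survey summary ("All" respondents, n=137): mean ± SD in kg.
DEFAULT_ELICITATION_SUMMARY = {
    "SQ": (7.1, 5.1),
    "BP": (4.4, 3.3),
    "DL": (8.1, 5.0),
    "Total": (17.5, 12.1),
}

#: Respondent role mix of the survey: 99 athletes, 31 athlete-coaches, 7 coaches.
DEFAULT_ROLE_MIX = {
    "athlete": 99 / 137,
    "athlete_coach": 31 / 137,
    "coach": 7 / 137,
}


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class ElicitationConfig:
    """Configuration of the synthetic meaningful-change survey."""

    n_respondents: int = 137
    outcomes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELICITATION_SUMMARY))
    role_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_MIX))
    truncate_at_zero: bool = False
    moment_match: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 2:
            raise ConfigurationError("n_respondents must be >= 2")
        for outcome, (loc, scale) in self.outcomes.items():
            if scale < 0:
                raise ConfigurationError(
                    f"negative scale for outcome {outcome!r}")
        total = sum(self.role_mix.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.role_mix.values()):
            raise ConfigurationError("role proportions must be >= 0 and sum to 1")


def _largest_remainder_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: p * n for k, p in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _truncnorm_parent(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal with the given moments."""

    def eqs(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a = -mu / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma,
                                     moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, _ = optimize.fsolve(eqs, x0=[mean, np.log(sd)],
                                        full_output=True)
    if ier != 1:
        # fall back to plain truncation of the target normal
        return mean, sd
    return float(sol[0]), float(np.exp(sol[1]))


def _moment_match(x: np.ndarray, loc: float, scale: float,
                  positive: bool) -> np.ndarray:
    """Affine-rescale draws to exact sample moments (optionally staying > 0)."""
    if scale == 0:
        return np.full_like(x, loc)
    for _ in range(200):
        sd = x.std(ddof=1)
        if sd == 0:
            x = x + np.linspace(-1e-6, 1e-6, x.size)
            sd = x.std(ddof=1)
        x = loc + scale * (x - x.mean()) / sd
        if not positive or (x > 0).all():
            return x
        x = np.clip(x, 1e-3 * scale, None)
    raise ConfigurationError(
        "could not moment-match under positivity; the configured mean/SD "
        "are incompatible with strictly positive values")


def generate_elicitation(config: ElicitationConfig) -> pd.DataFrame:
    """Generate one survey row per respondent per outcome.

    Returns a DataFrame with columns ``respondent_id, role, outcome,
    value_kg``.  With ``moment_match`` the realized sample mean and SD per
    outcome equal the configured values to within 1e-9; with
    ``truncate_at_zero`` all values are strictly positive (draws come from a
    zero-truncated normal whose parent parameters are solved so the truncated
    moments hit the target, which keeps the exact affine moment correction
    from crossing zero).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    counts = _largest_remainder_counts(config.role_mix, n)
    roles = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(roles)

    frames = []
    for outcome, (loc, scale) in config.outcomes.items():
        if scale == 0:
            values = np.full(n, float(loc))
        elif config.truncate_at_zero:
            mu, sigma = (_truncnorm_parent(loc, scale)
                         if config.moment_match else (loc, scale))
            a = -mu / sigma
            values = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma,
                                         size=n, random_state=rng)
        else:
            values = rng.normal(loc, scale, size=n)
        if config.moment_match and scale > 0:
            values = _moment_match(values, loc, scale,
                                   positive=config.truncate_at_zero)
        frames.append(pd.DataFrame({
            "respondent_id": np.arange(1, n + 1),
            "role": roles,
            "outcome": outcome,
            "value_kg": values,
        }))
    out = pd.concat(frames, ignore_index=True)
    if out["value_kg"].isna().any():
        raise AssertionError("generated elicitation contains missing values")
    return out


@dataclass(frozen=True)
class GroupConfig:
    """One intervention arm of a synthetic cohort.

    ``true_change`` and ``change_sd`` are per-lift (kg); ``pre`` maps lift to
    (location, scale) of the pre-intervention 1RM distribution (kg).
    ``slope`` is the regression of change on (pre - mean pre), shared across
    lifts.  Defaults emulate the published participant characteristics of the
    daily-max-plus-back-off arm.
    """

    label: str = "MAX_BOFF"
    n: int = 8
    protocol: str = "MAX_BOFF"
    true_change: dict[str, float] = field(
        default_factory=lambda: {"SQ": 12.0, "BP": 9.0, "DL": 12.0})
    change_sd: dict[str, float] = field(
        default_factory=lambda: {"SQ": 7.0, "BP": 5.0, "DL": 8.0})
    pre: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"SQ": (196.8, 29.9), "BP": (122.1, 17.5),
                                 "DL": (216.2, 44.1)})
    slope: float = 0.0
    body_mass: tuple[float, float] = (88.1, 6.8)
    sex: str = "M"
    amrap_rep_means: dict[str, float] = field(
        default_factory=lambda: {"SQ": 13.1, "BP": 16.7, "DL": 11.5})
    rpe_target: float = 9.25
    soreness_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"group {self.label!r}: n must be >= 1")
        if any(s < 0 for s in self.change_sd.values()):
            raise ConfigurationError("change-score SDs must be >= 0")
        if not 1 <= self.rpe_target <= 10:
            raise ConfigurationError("rpe_target must be in [1, 10]")


@dataclass(frozen=True)
class CohortConfig:
    """A study arm set plus study-level settings."""

    study: str = "study3"
    groups: tuple[GroupConfig, ...] = ()
    dropout_rate: float = 0.0
    n_weeks: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("at least one group is required")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")


@dataclass
class InterventionDataset:
    """Athlete-level scores plus per-session training logs.

    ``scores``: one row per participant per outcome (SQ, BP, DL, Total) with
    pre/post/change in kg, body mass, sex, Wilks points and strength class.
    ``sessions``: one row per working set with RPE and next-day soreness.
    """

    scores: pd.DataFrame
    sessions: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        s = self.scores
        if s.empty:  # e.g. full dropout
            return
        if not np.allclose(s["change_kg"], s["post_kg"] - s["pre_kg"]):
            raise AssertionError("change != post - pre")
        wide = s.pivot_table(index="participant_id", columns="lift",
                             values="change_kg", aggfunc="first")
        if not np.allclose(wide["Total"], wide[list(LIFTS)].sum(axis=1)):
            raise AssertionError("Total change != SQ + BP + DL")
        if len(self.sessions):
            sor = self.sessions["soreness_next_day"]
            if ((sor < 0) | (sor > 5)).any():
                raise AssertionError("soreness outside [0, 5]")
            rpe = self.sessions["rpe"]
            if ((rpe < 1) | (rpe > 10)).any():
                raise AssertionError("RPE outside [1, 10]")

    @property
    def participants(self) -> np.ndarray:
        return self.scores["participant_id"].unique()

    def to_csv(self, scores_path, sessions_path) -> None:
        self.scores.to_csv(scores_path, index=False)
        self.sessions.to_csv(sessions_path, index=False)

    @classmethod
    def from_csv(cls, scores_path, sessions_path=None) -> "InterventionDataset":
        scores = pd.read_csv(scores_path)
        sessions = (pd.read_csv(sessions_path) if sessions_path is not None
                    else pd.DataFrame(columns=_SESSION_COLUMNS))
        return cls(scores=scores, sessions=sessions)


_SESSION_COLUMNS = ["study", "group", "participant_id", "session_index",
                    "lift", "set_type", "reps", "load_kg", "rpe",
                    "soreness_next_day"]

# 2-3-1 weekly frequency: SQ on days 1 and 3, BP on all three, DL on day 2.
_DAY_LIFTS = {1: ("SQ", "BP"), 2: ("BP", "DL"), 3: ("SQ", "BP")}


def _simulate_sessions(rng, config: CohortConfig, group: GroupConfig,
                       pid: str, pre: dict[str, float]) -> list[dict]:
    proto = get_protocol(group.protocol)
    rows = []
    n_sessions = 3 * config.n_weeks
    for s in range(1, n_sessions + 1):
        day = (s - 1) % 3 + 1
        soreness = float(np.clip(rng.normal(group.soreness_mean, 0.5), 0, 5))
        for lift in _DAY_LIFTS[day]:
            daily_max = 0.95 * pre[lift] * (1 + rng.normal(0, 0.015))
            base = dict(study=config.study, group=group.label,
                        participant_id=pid, session_index=s, lift=lift,
                        soreness_next_day=round(soreness, 2))
            if proto.amrap is not None:
                reps = max(1, int(round(
                    rng.normal(group.amrap_rep_means[lift], 2.0))))
                rows.append(base | dict(
                    set_type="amrap", reps=reps,
                    load_kg=round(proto.amrap.load_fraction * pre[lift], 1),
                    rpe=float(np.clip(rng.normal(group.rpe_target, 0.15), 1, 10))))
            else:
                for _ in range(proto.main_sets):
                    rows.append(base | dict(
                        set_type="main", reps=proto.main_reps,
                        load_kg=round(daily_max, 1),
                        rpe=float(np.clip(rng.normal(group.rpe_target, 0.15),
                                          1, 10))))
                if proto.backoff is not None:
                    for _ in range(proto.backoff.sets):
                        rows.append(base | dict(
                            set_type="backoff", reps=proto.backoff.reps,
                            load_kg=round(
                                proto.backoff.load_fraction * daily_max, 1),
                            rpe=float(np.clip(rng.normal(6.6, 1.0), 1, 10))))
    return rows


def generate_cohort(config: CohortConfig) -> InterventionDataset:
    """Simulate a quasi-randomized cohort with the configured arm structure.

    Per participant and lift: pre ~ Normal(configured location, scale);
    change = true group mean + slope * (pre - group pre mean) + Normal(0, sd);
    Total rows are the sum of the three lifts.  Wilks points are computed from
    body mass and the pre total, and the strength class from the published
    class bands.
    """
    rng = np.random.default_rng(config.seed)
    score_rows: list[dict] = []
    session_rows: list[dict] = []
    for group in config.groups:
        for i in range(group.n):
            pid = f"{config.study}-{group.label}-{i + 1:02d}"
            body_mass = float(rng.normal(*group.body_mass))
            pre = {lift: float(rng.normal(*group.pre[lift])) for lift in LIFTS}
            change = {}
            for lift in LIFTS:
                noise = (rng.normal(0, group.change_sd[lift])
                         if group.change_sd[lift] > 0 else 0.0)
                change[lift] = (group.true_change[lift]
                                + group.slope * (pre[lift] - group.pre[lift][0])
                                + noise)
            pre["Total"] = sum(pre[l] for l in LIFTS)
            change["Total"] = sum(change[l] for l in LIFTS)
            wilks = wilks_score(body_mass, pre["Total"], group.sex)
            cls = strength_class(wilks)
            for outcome in OUTCOMES:
                score_rows.append(dict(
                    study=config.study, group=group.label,
                    participant_id=pid, lift=outcome,
                    pre_kg=pre[outcome], post_kg=pre[outcome] + change[outcome],
                    change_kg=change[outcome], body_mass_kg=body_mass,
                    sex=group.sex, wilks=wilks, strength_class=cls))
            session_rows.extend(
                _simulate_sessions(rng, config, group, pid, pre))
    dataset = InterventionDataset(
        scores=pd.DataFrame(score_rows),
        sessions=pd.DataFrame(session_rows, columns=_SESSION_COLUMNS))
    if config.dropout_rate > 0:
        dataset = apply_dropout(dataset, config.dropout_rate,
                                seed=int(rng.integers(2**31)))
    return dataset


def apply_dropout(data: InterventionDataset, rate: float,
                  seed: int) -> InterventionDataset:
    """Remove each participant independently with probability ``rate``.

    Dropout is completely at random (the real losses were due to facility
    closures, not treatment); all rows of a dropped participant vanish.
    """
    if not 0 <= rate < 1:
        raise ConfigurationError("dropout rate must be in [0, 1)")
    if rate == 0:
        return data
    rng = np.random.default_rng(seed)
    ids = data.participants
    keep = ids[rng.random(ids.size) >= rate]
    return InterventionDataset(
        scores=data.scores[data.scores["participant_id"].isin(keep)]
        .reset_index(drop=True),
        sessions=data.sessions[data.sessions["participant_id"].isin(keep)]
        .reset_index(drop=True))
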