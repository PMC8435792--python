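"""Training protocols, weekly volume accounting, Wilks scoring and group allocation.

The three minimal-dose protocols compared in the intervention arms:

* ``MAX`` — one near-maximal single ("daily max") at RPE 9–9.5 per session,
  on a 2-3-1 squat / bench press / deadlift weekly frequency.
* ``MAX_BOFF`` — the same daily-max single plus two back-off sets of three
  repetitions at 80% of the single's load.
* ``AMRAP`` — one as-many-repetitions-as-possible set at 70% 1RM terminated
  at RPE 9–9.5 (repetition count is autoregulated, hence variable).

Volume is counted in working repetitions per week, excluding warm-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BackoffRule",
    "AmrapRule",
    "ProtocolSpec",
    "StrengthClassTable",
    "PRESETS",
    "get_protocol",
    "wilks_score",
    "strength_class",
    "quasi_randomize",
    "weekly_reps",
    "relative_volume",
    "extrapolate_gain",
]

LIFTS = ("SQ", "BP", "DL")

# Classic Wilks polynomial coefficients (Wilks, 1994, as distributed by
# Powerlifting Australia and used in IPF-affiliated scoring before IPF
# points). Coefficient = 500 / (a + b x + c x^2 + d x^3 + e x^4 + f x^5)
# with x = body mass in kg. Swappable: pass a custom table to wilks_score.
WILKS_COEFFICIENTS = {
    "M": (-216.0475144, 16.2606339, -0.002388645, -0.00113732,
          7.01863e-06, -1.291e-08),
    "F": (594.31747775582, -27.23842536447, 0.82112226871, -0.00930733913,
          4.731582e-05, -9.054e-08),
}


@dataclass(frozen=True)
class BackoffRule:
    """Back-off work appended after the main set(s) of a session."""

    sets: int = 2
    reps: int = 3
    load_fraction: float = 0.8  # fraction of the daily-max single's load

    def __post_init__(self) -> None:
        if not 0 < self.load_fraction <= 1:
            raise ValueError("back-off load fraction must be in (0, 1]")
        if self.sets < 0 or self.reps < 0:
            raise ValueError("back-off sets/reps must be non-negative")


@dataclass(frozen=True)
class AmrapRule:
    """Autoregulated AMRAP set: fixed load fraction, stop at an RPE band."""

    load_fraction: float = 0.70
    stop_rpe: tuple[float, float] = (9.0, 9.5)

    def __post_init__(self) -> None:
        if not 0 < self.load_fraction <= 1:
            raise ValueError("AMRAP load fraction must be in (0, 1]")
        lo, hi = self.stop_rpe
        if not (1 <= lo <= hi <= 10):
            raise ValueError("stop RPE band must lie within [1, 10]")


@dataclass(frozen=True)
class ProtocolSpec:
    """One training protocol: weekly frequency plus per-session work.

    ``frequency`` maps lift -> training days per week (default 2-3-1 for
    SQ-BP-DL).  ``main_sets`` x ``main_reps`` is the prescribed main work per
    session; an ``amrap`` rule replaces fixed main work with an autoregulated
    set whose repetition count is not known in advance (and therefore excluded
    from deterministic weekly-repetition accounting).
    """

    label: str
    frequency: dict[str, int] = field(
        default_factory=lambda: {"SQ": 2, "BP": 3, "DL": 1})
    main_sets: int = 1
    main_reps: int = 1
    main_rpe: tuple[float, float] = (9.0, 9.5)
    backoff: BackoffRule | None = None
    amrap: AmrapRule | None = None

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.frequency.values()):
            raise ValueError("weekly frequencies must be >= 0")
        lo, hi = self.main_rpe
        if not (1 <= lo <= hi <= 10):
            raise ValueError("main RPE band must lie within [1, 10]")


PRESETS: dict[str, ProtocolSpec] = {
    "MAX": ProtocolSpec(label="MAX"),
    "MAX_BOFF": ProtocolSpec(label="MAX_BOFF", backoff=BackoffRule()),
    "AMRAP": ProtocolSpec(label="AMRAP", main_sets=0, main_reps=0,
                          amrap=AmrapRule()),
}


def get_protocol(name: str) -> ProtocolSpec:
    """Look up a built-in protocol preset by label."""
    try:
        return PRESETS[name.upper().replace("+", "_").replace("BOFF", "BOFF")]
    except KeyError:
        raise KeyError(f"unknown protocol {name!r}; presets: {sorted(PRESETS)}")


def wilks_score(body_mass: float, lifted: float, sex: str,
                coefficients: dict | None = None) -> float:
    """Wilks points for ``lifted`` kg at ``body_mass`` kg.

    points = lifted * 500 / poly(body_mass), linear in the load.  ``sex`` is
    "M" or "F"; a custom coefficient table may be supplied.
    """
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    if lifted < 0:
        raise ValueError("lifted load must be non-negative")
    table = WILKS_COEFFICIENTS if coefficients is None else coefficients
    try:
        a, b, c, d, e, f = table[sex.upper()[0]]
    except KeyError:
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    x = float(body_mass)
    denom = a + b * x + c * x**2 + d * x**3 + e * x**4 + f * x**5
    return float(lifted) * 500.0 / denom


@dataclass(frozen=True)
class StrengthClassTable:
    """Ordered, disjoint Wilks bands mapping to strength classes 1..k.

    The study's bands leave gaps (e.g. 341–349); values in a gap go to the
    band with the nearest boundary, ties to the lower band.  Values below the
    lowest band map to the lowest class, above the highest to the top class.
    """

    bands: tuple[tuple[float, float, int], ...] = (
        (300.0, 340.0, 1),
        (350.0, 400.0, 2),
        (410.0, 450.0, 3),
        (460.0, 500.0, 4),
        (510.0, 550.0, 5),
    )

    def __post_init__(self) -> None:
        prev_high = -np.inf
        for low, high, _ in self.bands:
            if low > high or low <= prev_high:
                raise ValueError("bands must be ascending and non-overlapping")
            prev_high = high

    def classify(self, wilks: float) -> int:
        if wilks <= 0:
            raise ValueError("Wilks score must be positive")
        bands = self.bands
        if wilks < bands[0][0]:
            return bands[0][2]  # below lowest band
        for i, (low, high, cls) in enumerate(bands):
            if low <= wilks <= high:
                return cls
            if wilks < low:  # in the gap between band i-1 and band i
                below_high = bands[i - 1][1]
                # nearest boundary; tie -> lower band
                if (wilks - below_high) <= (low - wilks):
                    return bands[i - 1][2]
                return cls
        return bands[-1][2]  # above highest band


DEFAULT_CLASS_TABLE = StrengthClassTable()


def strength_class(wilks: float,
                   table: StrengthClassTable = DEFAULT_CLASS_TABLE) -> int:
    """Strength class (1–5 by default) for a Wilks score."""
    return table.classify(wilks)


def quasi_randomize(wilks_scores, n_groups: int, seed: int,
                    table: StrengthClassTable = DEFAULT_CLASS_TABLE):
    """Strength-matched quasi-random allocation.

    Athletes are binned by strength class, shuffled within class (seeded) and
    dealt round-robin to groups, so that group strength levels are
    approximately matched while allocation within class is random.

    Returns an integer array of group indices (0..n_groups-1) aligned with
    the input order.
    """
    wilks_scores = np.asarray(wilks_scores, dtype=float)
    if wilks_scores.size == 0:
        raise ValueError("at least one athlete is required")
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    rng = np.random.default_rng(seed)
    classes = np.array([table.classify(w) for w in wilks_scores])
    assignment = np.empty(wilks_scores.size, dtype=int)
    for cls in np.unique(classes):
        idx = np.flatnonzero(classes == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % n_groups
    return assignment


def weekly_reps(protocol: ProtocolSpec) -> dict[str, dict[str, int]]:
    """Deterministic working repetitions per week, by lift.

    Returns ``{lift: {"main": m, "backoff": b, "total": m + b}}``.  AMRAP
    repetitions are autoregulated and excluded from the deterministic count.
    """
    out: dict[str, dict[str, int]] = {}
    for lift, freq in protocol.frequency.items():
        main = freq * protocol.main_sets * protocol.main_reps
        boff = 0
        if protocol.backoff is not None:
            boff = freq * protocol.backoff.sets * protocol.backoff.reps
        out[lift] = {"main": main, "backoff": boff, "total": main + boff}
    return out


def _total_weekly_reps(protocol: ProtocolSpec) -> int:
    return sum(v["total"] for v in weekly_reps(protocol).values())


def relative_volume(a: ProtocolSpec, b: ProtocolSpec) -> float:
    """Percent difference in total weekly repetitions of ``a`` relative to ``b``.

    100 * (reps(a) - reps(b)) / reps(b); e.g. the back-off protocol performs
    600% more volume than daily-max singles alone.
    """
    base = _total_weekly_reps(b)
    if base == 0:
        raise ValueError("baseline protocol has zero weekly repetitions")
    return 100.0 * (_total_weekly_reps(a) - base) / base


def extrapolate_gain(rate_kg_per_day: float, days: float) -> float:
    """Extrapolate a daily strength-gain rate (kg/day) over ``days`` days.

    Used to put elicited meaningful changes in context of observed long-term
    competition progression rates (e.g. 0.12 kg/day over a year = 43.8 kg).
    """
    return rate_kg_per_day * days
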