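"""Recording schedule, call/false-alarm event streams, and classifier scores.

Events are generated minute by minute within the recording schedule.
Target-species calls occur only at occupied site-seasons, as a Poisson
process with hourly rate ``lambda_c``; false alarms occur in every
recorded minute at every site with hourly rate ``lambda_f``.  A
classifier then assigns each event a "target signal probability" drawn
from a beta distribution whose shape depends on the event's latent truth
(target signal vs false alarm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import OccupancyState

__all__ = [
    "RecordingSchedule",
    "ClassifierSpec",
    "RateParams",
    "GOOD_CLASSIFIER",
    "BAD_CLASSIFIER",
    "EVENT_COLUMNS",
    "empty_event_table",
    "simulate_call_events",
    "simulate_false_alarm_events",
    "assign_target_signal_probabilities",
    "simulate_event_table",
]

#: Column order of an event table (one row per event-level detection).
EVENT_COLUMNS = ["site_id", "season", "day", "minute", "is_target", "score"]


@dataclass(frozen=True)
class RecordingSchedule:
    """Audio sampling design: ``minutes_per_day`` recorded minutes on each
    of ``days_per_season`` days, in each of ``n_seasons`` seasons."""

    days_per_season: int = 30
    minutes_per_day: int = 5
    n_seasons: int = 2

    def __post_init__(self) -> None:
        for name in ("days_per_season", "minutes_per_day", "n_seasons"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def minutes_per_season(self) -> int:
        return self.days_per_season * self.minutes_per_day


@dataclass(frozen=True)
class ClassifierSpec:
    """Beta shape parameters of the score distributions for true target
    signals and for false alarms."""

    target_alpha: float
    target_beta: float
    fa_alpha: float
    fa_beta: float
    label: str = "custom"

    def __post_init__(self) -> None:
        for name in ("target_alpha", "target_beta", "fa_alpha", "fa_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def mean_target_score(self) -> float:
        return self.target_alpha / (self.target_alpha + self.target_beta)

    @property
    def mean_fa_score(self) -> float:
        return self.fa_alpha / (self.fa_alpha + self.fa_beta)


#: Discriminative classifier: high scores for targets, low for false alarms.
GOOD_CLASSIFIER = ClassifierSpec(4.0, 1.0, 1.0, 4.0, label="good")
#: Uninformative classifier: scores centred on 0.5 for both event types.
BAD_CLASSIFIER = ClassifierSpec(3.0, 3.0, 3.0, 3.0, label="bad")


@dataclass(frozen=True)
class RateParams:
    """Hourly Poisson rates: species calls (``lambda_c``, at occupied
    sites) and soundscape false alarms (``lambda_f``, everywhere)."""

    lambda_c: float
    lambda_f: float = 48.0

    def __post_init__(self) -> None:
        if self.lambda_c < 0 or self.lambda_f < 0:
            raise ValueError("rates must be >= 0")


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": pd.Series(dtype=np.int64),
            "season": pd.Series(dtype=np.int64),
            "day": pd.Series(dtype=np.int64),
            "minute": pd.Series(dtype=np.int64),
            "is_target": pd.Series(dtype=np.int64),
            "score": pd.Series(dtype=float),
        }
    )


def _expand_minute_counts(
    counts: np.ndarray,
    site_ids: np.ndarray,
    seasons: np.ndarray,
    schedule: RecordingSchedule,
    is_target: int,
) -> pd.DataFrame:
    """Turn per-(unit, day, minute) counts into one event row per count.

    ``counts`` has shape (n_units, days, minutes); ``site_ids``/``seasons``
    give the 1-based site and season of each unit.
    """
    n_units, n_days, n_min = counts.shape
    flat = counts.ravel()
    idx = np.repeat(np.arange(flat.size), flat)
    unit = idx // (n_days * n_min)
    day = (idx // n_min) % n_days + 1
    minute = idx % n_min + 1
    return pd.DataFrame(
        {
            "site_id": site_ids[unit],
            "season": seasons[unit],
            "day": day,
            "minute": minute,
            "is_target": np.full(idx.size, is_target, dtype=np.int64),
            "score": np.full(idx.size, np.nan),
        }
    )


def simulate_call_events(
    occ: OccupancyState,
    schedule: RecordingSchedule,
    lambda_c: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw target-signal events for every recorded minute of every
    occupied site-season; unoccupied site-seasons produce none.

    Counts per minute are Poisson with mean ``lambda_c / 60``.
    """
    if lambda_c < 0:
        raise ValueError("lambda_c must be >= 0")
    if occ.n_seasons != schedule.n_seasons:
        raise ValueError("occupancy and schedule disagree on season count")
    rng = np.random.default_rng(rng)
    site_idx, season_idx = np.nonzero(occ.z)
    if site_idx.size == 0 or lambda_c == 0:
        return empty_event_table()
    counts = rng.poisson(
        lambda_c / 60.0,
        size=(site_idx.size, schedule.days_per_season, schedule.minutes_per_day),
    )
    return _expand_minute_counts(counts, site_idx + 1, season_idx + 1, schedule, 1)


def simulate_false_alarm_events(
    occ_or_sites: OccupancyState | int,
    schedule: RecordingSchedule,
    lambda_f: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw false-alarm events for every recorded minute of every site,
    regardless of occupancy, at per-minute rate ``lambda_f / 60``."""
    if lambda_f < 0:
        raise ValueError("lambda_f must be >= 0")
    if isinstance(occ_or_sites, OccupancyState):
        n_sites = occ_or_sites.n_sites
    else:
        n_sites = int(occ_or_sites)
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(rng)
    if lambda_f == 0:
        return empty_event_table()
    sites = np.repeat(np.arange(n_sites), schedule.n_seasons)
    seasons = np.tile(np.arange(schedule.n_seasons), n_sites)
    counts = rng.poisson(
        lambda_f / 60.0,
        size=(sites.size, schedule.days_per_season, schedule.minutes_per_day),
    )
    return _expand_minute_counts(counts, sites + 1, seasons + 1, schedule, 0)


def assign_target_signal_probabilities(
    events: pd.DataFrame,
    spec: ClassifierSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill the ``score`` column: Beta(target_alpha, target_beta) draws for
    target rows, Beta(fa_alpha, fa_beta) for false-alarm rows."""
    if "is_target" not in events.columns or events["is_target"].isna().any():
        raise ValueError("events must carry a latent is_target label")
    out = events.copy()
    tgt = out["is_target"].to_numpy(dtype=bool)
    rng = np.random.default_rng(rng)
    scores = np.empty(len(out))
    scores[tgt] = rng.beta(spec.target_alpha, spec.target_beta, tgt.sum())
    scores[~tgt] = rng.beta(spec.fa_alpha, spec.fa_beta, (~tgt).sum())
    out["score"] = scores
    return out


def simulate_event_table(
    occ: OccupancyState,
    schedule: RecordingSchedule,
    rates: RateParams,
    spec: ClassifierSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full soundscape simulation: calls + false alarms, scored.

    Convenience wrapper chaining :func:`simulate_call_events`,
    :func:`simulate_false_alarm_events` and
    :func:`assign_target_signal_probabilities`.
    """
    rng = np.random.default_rng(rng)
    calls = simulate_call_events(occ, schedule, rates.lambda_c, rng)
    alarms = simulate_false_alarm_events(occ, schedule, rates.lambda_f, rng)
    if len(calls) == 0 and len(alarms) == 0:
        return empty_event_table()
    events = pd.concat([calls, alarms], ignore_index=True)
    events = events.sort_values(
        ["site_id", "season", "day", "minute"], kind="stable", ignore_index=True
    )
    return assign_target_signal_probabilities(events, spec, rng)
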