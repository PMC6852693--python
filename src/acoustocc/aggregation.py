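"""Aggregate event-level detections into survey-level encounter histories.

All event scores within a survey window are combined in a
capture-recapture style product: with scores ``s_1 .. s_J``, the
probability that every detected event is a false alarm is
``prod_j (1 - s_j)``, so ``q = 1 - prod_j (1 - s_j)`` is the probability
that at least one event is a true target signal.  Unconfirmed surveys
are coded 1 (uncertain detection) when ``q`` meets the detection
threshold, else 0.  A randomly chosen subset of surveys is manually
confirmed: those are coded 2 (certain detection) when the survey truly
contains at least one target signal, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import OccupancyState
from .soundscape import RecordingSchedule

__all__ = [
    "AggregationConfig",
    "EncounterHistory",
    "RateSummary",
    "survey_detection_probability",
    "assign_confirmed_surveys",
    "build_encounter_history",
    "compute_survey_rates",
]


@dataclass(frozen=True)
class AggregationConfig:
    """Encounter-history construction choices.

    Parameters
    ----------
    aggregation_days
        Number of consecutive recording days lumped into one survey
        (the unit of closure).  Must divide the days per season.
    threshold
        Survey-level detection threshold on the aggregated probability
        ``q``; a survey is coded 1 when ``q >= threshold``.
    confirm_prop
        Proportion of all site-surveys designated for manual
        confirmation (the certain state).
    """

    aggregation_days: int = 1
    threshold: float = 0.95
    confirm_prop: float = 0.05

    def __post_init__(self) -> None:
        if self.aggregation_days < 1:
            raise ValueError("aggregation_days must be >= 1")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if not (0.0 <= self.confirm_prop <= 1.0):
            raise ValueError("confirm_prop must be in [0, 1]")


@dataclass(frozen=True)
class EncounterHistory:
    """Site x survey detection codes in {0, 1, 2} plus survey metadata.

    ``survey_meta`` has one row per survey with columns
    ``survey`` (1-based), ``season``, ``first_day`` and ``last_day``;
    ``confirmed`` marks the site-surveys designated for manual review.
    """

    codes: np.ndarray
    survey_meta: pd.DataFrame
    confirmed: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        confirmed = np.asarray(self.confirmed, dtype=bool)
        if codes.ndim != 2 or codes.shape != confirmed.shape:
            raise ValueError("codes and confirmed must be matching 2-d matrices")
        if not np.isin(codes, (0, 1, 2)).all():
            raise ValueError("codes must be in {0, 1, 2}")
        if ((codes == 2) & ~confirmed).any():
            raise ValueError("code 2 requires a confirmed survey")
        if len(self.survey_meta) != codes.shape[1]:
            raise ValueError("survey_meta length must equal the survey count")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "confirmed", confirmed)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.codes.shape[1]

    @property
    def survey_seasons(self) -> np.ndarray:
        """1-based season label of each survey, in survey order."""
        return self.survey_meta["season"].to_numpy()


@dataclass(frozen=True)
class RateSummary:
    """Survey-level detection rates; NaN marks an undefined rate (no
    occupied, or no unoccupied, site-surveys)."""

    tp_rate: float
    fp_rate: float


def survey_detection_probability(scores: Sequence[float]) -> float:
    """Probability that at least one event in a survey is a true target.

    Returns ``1 - prod_j (1 - score_j)``; an empty score list gives 0.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        return 0.0
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("scores must lie in [0, 1]")
    return float(-np.expm1(np.log1p(-scores).sum()))


def assign_confirmed_surveys(
    n_sites: int,
    n_surveys: int,
    confirm_prop: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniformly select ``floor(confirm_prop * n_sites * n_surveys)``
    site-survey units (without replacement) for manual confirmation."""
    if not (0.0 <= confirm_prop <= 1.0):
        raise ValueError("confirm_prop must be in [0, 1]")
    rng = np.random.default_rng(rng)
    total = n_sites * n_surveys
    k = int(np.floor(confirm_prop * total))
    mask = np.zeros(total, dtype=bool)
    if k > 0:
        mask[rng.choice(total, size=k, replace=False)] = True
    return mask.reshape(n_sites, n_surveys)


def _survey_layout(schedule: RecordingSchedule, cfg: AggregationConfig) -> pd.DataFrame:
    if schedule.days_per_season % cfg.aggregation_days != 0:
        raise ValueError(
            f"aggregation_days={cfg.aggregation_days} does not divide "
            f"days_per_season={schedule.days_per_season}"
        )
    per_season = schedule.days_per_season // cfg.aggregation_days
    rows = []
    survey = 1
    for season in range(1, schedule.n_seasons + 1):
        for block in range(per_season):
            first = block * cfg.aggregation_days + 1
            rows.append(
                {
                    "survey": survey,
                    "season": season,
                    "first_day": first,
                    "last_day": first + cfg.aggregation_days - 1,
                }
            )
            survey += 1
    return pd.DataFrame(rows)


def build_encounter_history(
    events: pd.DataFrame,
    occ: OccupancyState,
    schedule: RecordingSchedule,
    cfg: AggregationConfig,
    rng: np.random.Generator | None = None,
) -> EncounterHistory:
    """Collapse scored events into a three-state encounter history.

    Surveys are consecutive non-overlapping blocks of
    ``cfg.aggregation_days`` days within each season.  Unconfirmed
    surveys are thresholded on the aggregated probability ``q``;
    confirmed surveys are coded 2 exactly when they contain a true
    target signal (manual review cannot be fooled by false alarms).
    """
    rng = np.random.default_rng(rng)
    meta = _survey_layout(schedule, cfg)
    per_season = schedule.days_per_season // cfg.aggregation_days
    n_sites = occ.n_sites
    n_surveys = len(meta)

    log_comp = np.zeros((n_sites, n_surveys))
    has_target = np.zeros((n_sites, n_surveys), dtype=bool)
    if len(events):
        site = events["site_id"].to_numpy(dtype=np.int64) - 1
        season = events["season"].to_numpy(dtype=np.int64) - 1
        day = events["day"].to_numpy(dtype=np.int64) - 1
        score = events["score"].to_numpy(dtype=float)
        if np.isnan(score).any():
            raise ValueError("events must be scored before aggregation")
        if (score < 0).any() or (score > 1).any():
            raise ValueError("scores must lie in [0, 1]")
        survey = season * per_season + day // cfg.aggregation_days
        np.add.at(log_comp, (site, survey), np.log1p(-score))
        tgt = events["is_target"].to_numpy(dtype=bool)
        has_target[site[tgt], survey[tgt]] = True

    q = -np.expm1(log_comp)
    confirmed = assign_confirmed_surveys(n_sites, n_surveys, cfg.confirm_prop, rng)
    codes = np.where(q >= cfg.threshold, 1, 0).astype(np.int8)
    codes[confirmed] = np.where(has_target[confirmed], 2, 0)
    return EncounterHistory(codes=codes, survey_meta=meta, confirmed=confirmed)


def compute_survey_rates(eh: EncounterHistory, occ: OccupancyState) -> RateSummary:
    """True/false positive rates of the encounter history.

    The true positive rate is the fraction of site-surveys at occupied
    site-seasons with a detection (code 1 or 2); the false positive rate
    is the same fraction among unoccupied site-seasons.
    """
    seasons = eh.survey_seasons - 1
    if seasons.max() >= occ.n_seasons or eh.n_sites != occ.n_sites:
        raise ValueError("encounter history and occupancy dimensions disagree")
    occupied = occ.z[:, seasons].astype(bool)
    detected = eh.codes > 0

    def _rate(mask: np.ndarray) -> float:
        return float(detected[mask].mean()) if mask.any() else float("nan")

    return RateSummary(tp_rate=_rate(occupied), fp_rate=_rate(~occupied))
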