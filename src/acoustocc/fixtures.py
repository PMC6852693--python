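"""Deterministic worked example of the aggregation rule.

One site, one season, two 1-day surveys.  Survey 1 holds three
low-scoring false alarms (0.15, 0.04, 0.11), so the aggregated
probability that at least one event is a target is
1 - 0.85 x 0.96 x 0.89 = 0.27.  Survey 2 holds three high-scoring
target signals (0.56, 0.88, 0.71) with aggregated probability
1 - 0.44 x 0.12 x 0.29 ~= 0.98.  At a 0.95 survey-level detection
threshold the encounter history is therefore "01".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import AggregationConfig, EncounterHistory, _survey_layout
from .dynamics import OccupancyState
from .soundscape import RecordingSchedule

__all__ = ["WorkedExample", "make_worked_example"]

SURVEY1_SCORES = (0.15, 0.04, 0.11)
SURVEY2_SCORES = (0.56, 0.88, 0.71)


@dataclass(frozen=True)
class WorkedExample:
    """Inputs plus the expected aggregation output at threshold 0.95."""

    events: pd.DataFrame
    occupancy: OccupancyState
    schedule: RecordingSchedule
    config: AggregationConfig
    expected: EncounterHistory

    @property
    def expected_history(self) -> str:
        return "".join(str(c) for c in self.expected.codes[0])


def make_worked_example() -> WorkedExample:
    """Build the two-survey example event table and its expected history."""
    schedule = RecordingSchedule(days_per_season=2, minutes_per_day=5, n_seasons=1)
    config = AggregationConfig(aggregation_days=1, threshold=0.95, confirm_prop=0.0)
    rows = []
    for day, scores, is_target in (
        (1, SURVEY1_SCORES, 0),
        (2, SURVEY2_SCORES, 1),
    ):
        for minute, score in enumerate(scores, start=1):
            rows.append(
                {
                    "site_id": 1,
                    "season": 1,
                    "day": day,
                    "minute": minute,
                    "is_target": is_target,
                    "score": score,
                }
            )
    events = pd.DataFrame(rows)
    occupancy = OccupancyState(np.array([[1]]))
    expected = EncounterHistory(
        codes=np.array([[0, 1]], dtype=np.int8),
        survey_meta=_survey_layout(schedule, config),
        confirmed=np.zeros((1, 2), dtype=bool),
    )
    return WorkedExample(
        events=events,
        occupancy=occupancy,
        schedule=schedule,
        config=config,
        expected=expected,
    )
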