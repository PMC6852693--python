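"""Serialization of tables, fit results and run manifests.

Event tables, occupancy tables and encounter histories travel as plain
CSV (full double precision); fit results and manifests as JSON.  An
encounter history is a CSV of codes plus a JSON sidecar holding the
survey -> (season, day range) map and the confirmed mask, which
together make the history self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import EncounterHistory
from .dynamics import OccupancyState
from .miller import FitResult, MillerParams
from .soundscape import EVENT_COLUMNS

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_occupancy",
    "write_occupancy",
    "read_encounter_history",
    "write_encounter_history",
    "write_fit_result",
    "read_fit_result",
    "RunManifest",
]


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return events[EVENT_COLUMNS]


def write_occupancy(occ: OccupancyState, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index=False)


def read_occupancy(path: str | Path) -> OccupancyState:
    frame = pd.read_csv(path)
    n_sites = int(frame["site_id"].max())
    n_seasons = int(frame["season"].max())
    z = np.zeros((n_sites, n_seasons), dtype=np.int8)
    z[frame["site_id"] - 1, frame["season"] - 1] = frame["occupied"]
    return OccupancyState(z)


def _sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.json")


def write_encounter_history(eh: EncounterHistory, path: str | Path) -> None:
    """CSV of codes (one survey column per survey) + JSON sidecar."""
    cols = {f"survey_{m.survey}": eh.codes[:, i] for i, m in enumerate(eh.survey_meta.itertuples())}
    frame = pd.DataFrame({"site_id": np.arange(1, eh.n_sites + 1), **cols})
    frame.to_csv(path, index=False)
    sidecar = {
        "surveys": eh.survey_meta.to_dict(orient="records"),
        "confirmed": eh.confirmed.astype(int).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_encounter_history(path: str | Path) -> EncounterHistory:
    frame = pd.read_csv(path)
    survey_cols = [c for c in frame.columns if c.startswith("survey_")]
    codes = frame[survey_cols].to_numpy(dtype=np.int8)
    sidecar = json.loads(_sidecar_path(path).read_text())
    meta = pd.DataFrame(sidecar["surveys"])
    confirmed = np.asarray(sidecar["confirmed"], dtype=bool)
    return EncounterHistory(codes=codes, survey_meta=meta, confirmed=confirmed)


def write_fit_result(fit: FitResult, path: str | Path) -> None:
    payload = {
        "estimates": asdict(fit.estimates),
        "neg_log_lik": fit.neg_log_lik,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "boundary_flags": fit.boundary_flags,
        "message": fit.message,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_result(path: str | Path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    return FitResult(
        estimates=MillerParams(**payload["estimates"]),
        neg_log_lik=payload["neg_log_lik"],
        converged=payload["converged"],
        n_iterations=payload["n_iterations"],
        boundary_flags=payload["boundary_flags"],
        message=payload.get("message", ""),
    )


@dataclass(frozen=True)
class RunManifest:
    """Record of one run, sufficient to reproduce its outputs."""

    config: dict
    master_seed: int
    outputs: list[str] = field(default_factory=list)
    software_version: str = ""
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
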