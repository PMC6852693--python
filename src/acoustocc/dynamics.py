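"""Latent multi-season occupancy dynamics.

A site is occupied in season 1 with probability ``psi``.  Between
consecutive seasons an occupied site goes extinct with probability
``epsilon`` and an unoccupied site is colonized with probability
``gamma`` (first-order Markov dynamics, sites independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DynamicsParams",
    "OccupancyState",
    "simulate_occupancy",
    "season_occupancy_prob",
]


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class DynamicsParams:
    """State parameters of the dynamic occupancy process.

    Parameters
    ----------
    psi
        Initial (season 1) occupancy probability.
    gamma
        Colonization probability per season-to-season transition.
    epsilon
        Extinction probability per season-to-season transition.
    """

    psi: float
    gamma: float
    epsilon: float

    def __post_init__(self) -> None:
        _check_probability("psi", self.psi)
        _check_probability("gamma", self.gamma)
        _check_probability("epsilon", self.epsilon)


@dataclass(frozen=True)
class OccupancyState:
    """Latent presence/absence matrix, ``z[site, season] in {0, 1}``."""

    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z)
        if z.ndim != 2:
            raise ValueError("z must be a 2-d (site x season) matrix")
        if not np.isin(z, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")
        object.__setattr__(self, "z", z.astype(np.int8))

    @property
    def n_sites(self) -> int:
        return self.z.shape[0]

    @property
    def n_seasons(self) -> int:
        return self.z.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns site_id, season, occupied (1-based ids)."""
        sites, seasons = np.indices(self.z.shape)
        return pd.DataFrame(
            {
                "site_id": sites.ravel() + 1,
                "season": seasons.ravel() + 1,
                "occupied": self.z.ravel(),
            }
        )


def simulate_occupancy(
    params: DynamicsParams,
    n_sites: int,
    n_seasons: int = 2,
    rng: np.random.Generator | None = None,
) -> OccupancyState:
    """Simulate latent occupancy for ``n_sites`` sites over ``n_seasons`` seasons.

    Season-1 states are iid Bernoulli(psi); each later season applies the
    extinction/colonization kernel to the previous season's state.
    """
    if n_sites < 1 or n_seasons < 1:
        raise ValueError("n_sites and n_seasons must be >= 1")
    rng = np.random.default_rng(rng)
    z = np.empty((n_sites, n_seasons), dtype=np.int8)
    z[:, 0] = rng.random(n_sites) < params.psi
    for s in range(1, n_seasons):
        prev = z[:, s - 1]
        p_occ = np.where(prev == 1, 1.0 - params.epsilon, params.gamma)
        z[:, s] = rng.random(n_sites) < p_occ
    return OccupancyState(z)


def season_occupancy_prob(params: DynamicsParams, season: int) -> float:
    """Marginal occupancy probability for a given season (1-based).

    Season 1 returns ``psi``; later seasons follow the recursion
    ``psi_{s+1} = psi_s (1 - epsilon) + (1 - psi_s) gamma``.
    """
    if season < 1:
        raise ValueError("season must be >= 1")
    p = params.psi
    for _ in range(season - 1):
        p = p * (1.0 - params.epsilon) + (1.0 - p) * params.gamma
    return p
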