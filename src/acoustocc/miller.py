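"""Multi-state dynamic occupancy model with false positives.

Encounter histories use three survey-level detection states: 0 (no
detection), 1 (uncertain, automated-only detection) and 2 (certain,
manually verified detection).  Conditional on the latent state the
observation model is

    occupied:    P(0) = 1 - p11,  P(1) = p11 (1 - b),  P(2) = p11 b
    unoccupied:  P(0) = 1 - p10,  P(1) = p10,          P(2) = 0

so false positives (uncertain detections where the species is absent)
are admitted through ``p10`` while certain detections anchor the
occupied state.  Latent dynamics follow the usual first-order occupancy
process (``psi``, ``gamma``, ``epsilon``) with closure within seasons.
The site likelihood marginalises the latent per-season states with a
forward recursion in log space; maximum-likelihood estimates are found
by quasi-Newton minimisation of the joint negative log-likelihood on
the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .aggregation import EncounterHistory

__all__ = [
    "MillerParams",
    "FitResult",
    "PARAM_NAMES",
    "survey_observation_probability",
    "site_history_likelihood",
    "negative_log_likelihood",
    "fit_miller_model",
]

PARAM_NAMES = ("psi", "gamma", "epsilon", "p10", "p11", "b")


@dataclass(frozen=True)
class MillerParams:
    """The six parameters of the model (all probabilities).

    ``psi``/``gamma``/``epsilon`` govern the latent dynamics; ``p10`` is
    the survey-level false positive probability at unoccupied sites,
    ``p11`` the survey-level detection probability at occupied sites and
    ``b`` the probability that a detection at an occupied site is
    certain (verified).
    """

    psi: float
    gamma: float
    epsilon: float
    p10: float
    p11: float
    b: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "MillerParams":
        return cls(*(float(v) for v in arr))


@dataclass(frozen=True)
class FitResult:
    estimates: MillerParams
    neg_log_lik: float
    converged: bool
    n_iterations: int
    boundary_flags: dict[str, bool] = field(default_factory=dict)
    message: str = ""


def survey_observation_probability(
    code: int, occupied: bool, params: MillerParams
) -> float:
    """P(survey code | latent occupancy state)."""
    if code not in (0, 1, 2):
        raise ValueError(f"invalid survey code {code!r}")
    if occupied:
        return (
            1.0 - params.p11,
            params.p11 * (1.0 - params.b),
            params.p11 * params.b,
        )[code]
    return (1.0 - params.p10, params.p10, 0.0)[code]


def _code_counts(codes: np.ndarray, seasons: np.ndarray) -> np.ndarray:
    """Per-site, per-season counts of each code; shape (3, n_sites, S).

    ``codes`` is (n_sites, n_surveys); ``seasons`` gives each survey's
    1-based season.  Sufficient statistics for an intercept-only model:
    within a season the likelihood depends only on how many surveys
    produced each code.
    """
    codes = np.atleast_2d(np.asarray(codes))
    seasons = np.asarray(seasons, dtype=np.int64)
    n_seasons = int(seasons.max())
    counts = np.zeros((3, codes.shape[0], n_seasons), dtype=np.int64)
    for c in range(3):
        np.add.at(
            counts[c].T, seasons - 1, (codes == c).T.astype(np.int64)
        )
    return counts


def _safe_log(x: np.ndarray | float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _season_log_obs(counts: np.ndarray, obs_probs: np.ndarray) -> np.ndarray:
    """log P(all codes in a season | z) for z=0,1; shape (2, n_sites, S).

    ``obs_probs`` is a (2, 3) matrix of P(code | z).  Zero observation
    probabilities only contribute where their code count is positive.
    """
    logp = _safe_log(obs_probs)  # (2, 3)
    out = np.zeros((2,) + counts.shape[1:])
    for z in (0, 1):
        for c in range(3):
            if np.isneginf(logp[z, c]):
                out[z] += np.where(counts[c] > 0, -np.inf, 0.0)
            else:
                out[z] += counts[c] * logp[z, c]
    return out


def _obs_matrix(params: MillerParams) -> np.ndarray:
    return np.array(
        [
            [1.0 - params.p10, params.p10, 0.0],
            [
                1.0 - params.p11,
                params.p11 * (1.0 - params.b),
                params.p11 * params.b,
            ],
        ]
    )


def _site_log_likelihoods(counts: np.ndarray, params: MillerParams) -> np.ndarray:
    """Per-site log-likelihood via a forward recursion over seasons."""
    log_obs = _season_log_obs(counts, _obs_matrix(params))
    psi, gamma, eps = params.psi, params.gamma, params.epsilon
    la0 = _safe_log(1.0 - psi) + log_obs[0, :, 0]
    la1 = _safe_log(psi) + log_obs[1, :, 0]
    for s in range(1, counts.shape[2]):
        new0 = np.logaddexp(la0 + _safe_log(1.0 - gamma), la1 + _safe_log(eps))
        new1 = np.logaddexp(la0 + _safe_log(gamma), la1 + _safe_log(1.0 - eps))
        la0 = new0 + log_obs[0, :, s]
        la1 = new1 + log_obs[1, :, s]
    return np.logaddexp(la0, la1)


def site_history_likelihood(
    codes: Sequence[int],
    seasons: Sequence[int],
    params: MillerParams,
) -> float:
    """Likelihood of one site's code sequence, marginalised over all
    latent occupancy sequences.

    ``seasons`` labels each survey with its (1-based) season; closure is
    assumed within a season.  Impossible data (e.g. a certain detection
    when ``p11 * b = 0`` and occupancy cannot explain it) yield 0.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if not np.isin(codes, (0, 1, 2)).all():
        raise ValueError("codes must be in {0, 1, 2}")
    counts = _code_counts(codes[None, :], np.asarray(seasons))
    return float(np.exp(_site_log_likelihoods(counts, params)[0]))


def negative_log_likelihood(
    eh: EncounterHistory | np.ndarray,
    params: MillerParams,
    seasons: Sequence[int] | None = None,
) -> float:
    """Joint negative log-likelihood over sites (sites independent).

    Accepts an :class:`EncounterHistory` or a raw code matrix plus
    per-survey season labels.  Returns ``inf`` when any site's history
    has zero likelihood under ``params``.
    """
    if isinstance(eh, EncounterHistory):
        codes, seasons = eh.codes, eh.survey_seasons
    else:
        codes = np.asarray(eh)
        if seasons is None:
            raise ValueError("season labels are required with a raw code matrix")
    counts = _code_counts(codes, np.asarray(seasons))
    ll = _site_log_likelihoods(counts, params)
    if np.isneginf(ll).any():
        return float("inf")
    return float(-ll.sum())


_CLIP = 1e-12


def fit_miller_model(
    eh: EncounterHistory | np.ndarray,
    init: MillerParams | None = None,
    seasons: Sequence[int] | None = None,
    *,
    gtol: float = 1e-5,
    ftol: float = 1e-10,
    maxiter: int = 1000,
    boundary_tol: float = 1e-3,
    grad_flag_tol: float = 1e-5,
) -> FitResult:
    """Maximum-likelihood fit of the six model parameters.

    Optimisation runs unconstrained on the logit scale (L-BFGS-B with a
    finite-difference gradient); probabilities are kept a hair inside
    (0, 1) during the search so a transiently impossible configuration
    incurs a large finite penalty instead of an infinite one.  The
    convergence flag requires optimizer success, a finite reported
    likelihood and a small projected gradient — ``grad_flag_tol`` is a
    per-site tolerance (the joint NLL and its gradient scale with the
    number of sites); estimates within ``boundary_tol`` of 0 or 1 are
    flagged.  A history with no variation
    at all (a single repeated code) is reported as non-converged.
    """
    if isinstance(eh, EncounterHistory):
        codes, seasons = eh.codes, eh.survey_seasons
    else:
        codes = np.atleast_2d(np.asarray(eh))
        if seasons is None:
            raise ValueError("season labels are required with a raw code matrix")
    if codes.size == 0:
        raise ValueError("encounter history is empty")
    counts = _code_counts(codes, np.asarray(seasons))

    if init is None:
        init = MillerParams(0.5, 0.3, 0.3, 0.2, 0.5, 0.3)
    theta0 = logit(np.clip(init.to_array(), 1e-6, 1.0 - 1e-6))

    def objective(theta: np.ndarray) -> float:
        p = np.clip(expit(theta), _CLIP, 1.0 - _CLIP)
        ll = _site_log_likelihoods(counts, MillerParams.from_array(p))
        # clip keeps the surface finite if a site is numerically impossible
        return float(-np.maximum(ll, -1e6).sum())

    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        options={"gtol": gtol, "ftol": ftol, "maxiter": maxiter},
    )
    estimates = MillerParams.from_array(expit(res.x))
    nll = negative_log_likelihood(codes, estimates, seasons)
    flags = {
        name: bool(v < boundary_tol or v > 1.0 - boundary_tol)
        for name, v in zip(PARAM_NAMES, estimates.to_array())
    }
    degenerate = np.unique(codes).size == 1
    converged = (
        bool(res.success)
        and np.isfinite(nll)
        and float(np.max(np.abs(res.jac))) <= grad_flag_tol * codes.shape[0]
        and not degenerate
    )
    return FitResult(
        estimates=estimates,
        neg_log_lik=nll,
        converged=converged,
        n_iterations=int(res.nit),
        boundary_flags=flags,
        message=str(res.message),
    )
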