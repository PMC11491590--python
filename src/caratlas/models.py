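"""Likelihoods and log-posterior for the incidence and excess-hazard models.

Two area-level models share the same Leroux CAR spatial prior:

*Incidence.*  Observed case counts ``y_i`` with externally standardized
expected counts ``E_i`` follow

    y_i ~ Poisson(E_i * exp(mu + S_i)),      SIR_i = exp(mu + S_i)

so with expected counts built from national rates the national average
corresponds to a standardized incidence ratio (SIR) of 1.

*Excess hazard (relative survival).*  Deaths ``d_ij`` in area ``i`` and
follow-up interval ``j``, with expected background deaths ``e_ij`` from
population life tables and person-time ``t_ij``, follow the
piecewise-constant excess-hazard Poisson form

    d_ij ~ Poisson(e_ij + t_ij * lambda_j * exp(S_i)),   EHR_i = exp(S_i)

where the interval baselines ``lambda_j`` absorb the national average
excess hazard, so the excess hazard ratio (EHR) is 1 at the national
reference.

Hyperpriors (weakly informative, proper): sigma ~ half-Normal(0, 1) on
the standard-deviation scale, rho ~ Uniform(0, 1), and mu and each
log(lambda_j) ~ Normal(0, 10^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .graph import RegionGraph, ValidationError

__all__ = [
    "IncidenceData",
    "SurvivalData",
    "ModelParams",
    "PriorConfig",
    "incidence_loglik",
    "excess_hazard_loglik",
    "car_logprior",
    "log_posterior",
]


@dataclass(frozen=True)
class IncidenceData:
    """Per-area observed and expected case counts."""

    area_ids: tuple[str, ...]
    observed: np.ndarray  # y_i, non-negative integers
    expected: np.ndarray  # E_i > 0

    def __post_init__(self) -> None:
        y = np.asarray(self.observed, dtype=float)
        e = np.asarray(self.expected, dtype=float)
        if y.shape != e.shape or y.ndim != 1 or len(self.area_ids) != y.size:
            raise ValidationError("observed/expected/area_ids lengths differ")
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValidationError("observed counts must be non-negative integers")
        if np.any(e <= 0) or not np.all(np.isfinite(e)):
            raise ValidationError("expected counts must be positive and finite")
        object.__setattr__(self, "observed", y)
        object.__setattr__(self, "expected", e)

    @property
    def n(self) -> int:
        return len(self.area_ids)


@dataclass(frozen=True)
class SurvivalData:
    """Deaths, expected background deaths and person-time by area and interval.

    Arrays are (n_areas, n_intervals).
    """

    area_ids: tuple[str, ...]
    deaths: np.ndarray          # d_ij
    expected_deaths: np.ndarray  # e_ij >= 0
    person_time: np.ndarray      # t_ij > 0

    def __post_init__(self) -> None:
        d = np.asarray(self.deaths, dtype=float)
        e = np.asarray(self.expected_deaths, dtype=float)
        t = np.asarray(self.person_time, dtype=float)
        if not (d.shape == e.shape == t.shape) or d.ndim != 2:
            raise ValidationError("deaths/expected_deaths/person_time shapes differ")
        if d.shape[0] != len(self.area_ids):
            raise ValidationError("area_ids length does not match data rows")
        if np.any(d < 0) or np.any(d != np.round(d)):
            raise ValidationError("deaths must be non-negative integers")
        if np.any(e < 0):
            raise ValidationError("expected background deaths must be >= 0")
        if np.any(t <= 0):
            raise ValidationError("person-time must be positive")
        object.__setattr__(self, "deaths", d)
        object.__setattr__(self, "expected_deaths", e)
        object.__setattr__(self, "person_time", t)

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def n_intervals(self) -> int:
        return self.deaths.shape[1]


@dataclass
class ModelParams:
    """Current parameter state for either model.

    ``mu`` is the global log-ratio intercept (incidence); ``lam`` holds
    the per-interval baseline excess hazards (survival); ``S`` is the
    spatial random-effect vector on the log-ratio scale.
    """

    S: np.ndarray
    rho: float
    sigma2: float
    mu: float = 0.0
    lam: np.ndarray | None = None


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings; defaults are weakly informative and proper."""

    sigma_halfnormal_scale: float = 1.0
    mu_sd: float = 10.0
    log_lambda_sd: float = 10.0


def incidence_loglik(data: IncidenceData, mu: float, S: np.ndarray) -> float:
    """Poisson log-likelihood of the incidence model, log(y!) included."""
    S = np.asarray(S, dtype=float)
    if S.shape != (data.n,):
        raise ValidationError(
            f"S has length {S.size}, expected {data.n}"
        )
    eta = np.log(data.expected) + mu + S
    return float(np.sum(data.observed * eta - np.exp(eta) - gammaln(data.observed + 1.0)))


def excess_hazard_loglik(data: SurvivalData, lam: np.ndarray, S: np.ndarray) -> float:
    """Poisson log-likelihood of the piecewise excess-hazard model.

    Cells where the mean is zero but deaths were observed make the
    likelihood ``-inf`` (returned, not raised).
    """
    S = np.asarray(S, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if S.shape != (data.n,):
        raise ValidationError(f"S has length {S.size}, expected {data.n}")
    if lam.shape != (data.n_intervals,):
        raise ValidationError(
            f"lambda has length {lam.size}, expected {data.n_intervals}"
        )
    mean = data.expected_deaths + data.person_time * lam[None, :] * np.exp(S)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = data.deaths * np.log(mean)
    # Poisson(0) at 0 contributes 0; at d>0 it is -inf
    term = np.where((mean == 0) & (data.deaths == 0), 0.0, term)
    return float(np.sum(term - mean - gammaln(data.deaths + 1.0)))


def car_logprior(S: np.ndarray, graph: RegionGraph, rho: float, sigma2: float,
                 struct_eigvals: np.ndarray | None = None) -> float:
    """Log density of S under the Leroux CAR prior N(0, Q(rho, sigma2)^{-1}).

    Uses the eigenvalue identity log det R(rho) = sum log(rho*g_k + 1 - rho)
    with g_k the eigenvalues of D - W; pass ``struct_eigvals`` to avoid
    recomputing them.
    """
    S = np.asarray(S, dtype=float)
    n = graph.n
    if S.shape != (n,):
        raise ValidationError(f"S has length {S.size}, expected {n}")
    if struct_eigvals is None:
        from scipy.linalg import eigh
        DW = (np.diag(graph.degrees()) - graph.adjacency().toarray())
        struct_eigvals = eigh(DW, eigvals_only=True)
    logdet_R = float(np.sum(np.log(rho * struct_eigvals + (1.0 - rho))))
    i, j = graph.edge_index_arrays()
    quad = rho * float(np.sum((S[i] - S[j]) ** 2)) + (1.0 - rho) * float(S @ S)
    return 0.5 * (logdet_R - n * np.log(2.0 * np.pi * sigma2)) - quad / (2.0 * sigma2)


def _normal_logpdf(x: float, sd: float) -> float:
    return -0.5 * np.log(2.0 * np.pi * sd * sd) - 0.5 * (x / sd) ** 2


def hyper_logprior(params: ModelParams, priors: PriorConfig) -> float:
    """Log hyperprior density in the natural parameterization.

    half-Normal on sigma, Uniform(0,1) on rho (contributes 0 on its
    support), Normal on mu and log(lambda_j).
    """
    sigma = np.sqrt(params.sigma2)
    lp = (
        0.5 * np.log(2.0 / np.pi)
        - np.log(priors.sigma_halfnormal_scale)
        - 0.5 * (sigma / priors.sigma_halfnormal_scale) ** 2
    )
    if params.lam is None:
        lp += _normal_logpdf(params.mu, priors.mu_sd)
    else:
        lp += float(sum(_normal_logpdf(np.log(l), priors.log_lambda_sd)
                        for l in params.lam))
    return lp


def log_posterior(params: ModelParams, data, graph: RegionGraph,
                  priors: PriorConfig | None = None,
                  struct_eigvals: np.ndarray | None = None) -> float:
    """Unnormalized log posterior: likelihood + CAR prior + hyperpriors."""
    priors = priors or PriorConfig()
    if isinstance(data, IncidenceData):
        ll = incidence_loglik(data, params.mu, params.S)
    elif isinstance(data, SurvivalData):
        if params.lam is None:
            raise ValidationError("survival model requires lambda baselines")
        ll = excess_hazard_loglik(data, params.lam, params.S)
    else:
        raise ValidationError(f"unsupported data type {type(data).__name__}")
    if tuple(data.area_ids) != tuple(graph.area_ids):
        raise ValidationError("data and graph area ids disagree")
    lp = car_logprior(params.S, graph, params.rho, params.sigma2, struct_eigvals)
    return ll + lp + hyper_logprior(params, priors)
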