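"""Posterior summaries: median, credible intervals, PPD, difference class.

The atlas publishes, per area, the posterior median of the ratio-scale
measure (SIR or EHR), equal-tailed 60% and 80% credible intervals, and
the posterior probability of difference (PPD): the proportion of
posterior draws above the national-average reference of 1.  Folding the
PPD as max(p, 1 - p) gives a direction-free confidence that the area
differs from the average — the quantity on the V-plot's y-axis.

Quantiles use linear interpolation between order statistics (the
"type 7" rule), so interval endpoints are continuous in the draws and
reproducible across ecosystems.  Draws exactly equal to the PPD
reference count as half, removing directional bias in the tie case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ValidationError
from .mcmc import PosteriorDraws

__all__ = [
    "AreaSummary",
    "point_estimate",
    "credible_interval",
    "ppd",
    "v_confidence",
    "classify_difference",
    "summarize_all",
]

CATEGORIES = ("likely_higher", "likely_lower", "uncertain")


@dataclass(frozen=True)
class AreaSummary:
    area_id: str
    point: float
    ci60: tuple[float, float]
    ci80: tuple[float, float]
    ppd: float
    v_conf: float
    category: str

    def __post_init__(self) -> None:
        if not (self.ci80[0] <= self.ci60[0] <= self.point
                <= self.ci60[1] <= self.ci80[1]):
            raise ValidationError(
                f"intervals for {self.area_id} are not nested around the median"
            )
        if not 0.0 <= self.ppd <= 1.0:
            raise ValidationError("ppd outside [0, 1]")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


def _as_draws(draws) -> np.ndarray:
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValidationError("empty draws")
    return x


def point_estimate(draws) -> float:
    """Posterior median (type-7 sample median) of ratio-scale draws."""
    x = _as_draws(draws)
    if np.any(x <= 0):
        raise ValidationError("ratio-scale draws must be positive")
    return float(np.median(x))


def credible_interval(draws, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval at ``level`` percent."""
    if not 0.0 < level < 100.0:
        raise ValueError(f"level must be in (0, 100), got {level}")
    x = _as_draws(draws)
    if x.size < 2:
        raise ValidationError("need at least 2 draws for an interval")
    tail = (1.0 - level / 100.0) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])  # type-7 interpolation
    return float(lo), float(hi)


def ppd(draws, reference: float = 1.0) -> float:
    """Posterior probability that the measure exceeds ``reference``.

    The proportion of draws strictly above the reference; draws exactly
    equal to it count as half.
    """
    x = _as_draws(draws)
    above = np.count_nonzero(x > reference)
    ties = np.count_nonzero(x == reference)
    return float((above + 0.5 * ties) / x.size)


def v_confidence(p: float) -> float:
    """Folded confidence max(p, 1-p) in [0.5, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"ppd must be in [0, 1], got {p}")
    return max(p, 1.0 - p)


def classify_difference(p: float, thresholds: tuple[float, float] = (0.2, 0.8)) -> str:
    """'likely_higher' / 'likely_lower' / 'uncertain' from the PPD."""
    low, high = thresholds
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"invalid thresholds {thresholds}")
    if p >= high:
        return "likely_higher"
    if p <= low:
        return "likely_lower"
    return "uncertain"


def summarize_one(area_id: str, draws, reference: float = 1.0,
                  thresholds: tuple[float, float] = (0.2, 0.8)) -> AreaSummary:
    p = ppd(draws, reference)
    return AreaSummary(
        area_id=area_id,
        point=point_estimate(draws),
        ci60=credible_interval(draws, 60),
        ci80=credible_interval(draws, 80),
        ppd=p,
        v_conf=v_confidence(p),
        category=classify_difference(p, thresholds),
    )


def summarize_all(draws: PosteriorDraws, reference: float = 1.0,
                  thresholds: tuple[float, float] = (0.2, 0.8)) -> list[AreaSummary]:
    """One :class:`AreaSummary` per area, in the draws' area order."""
    return [
        summarize_one(aid, draws.draws[:, k], reference, thresholds)
        for k, aid in enumerate(draws.area_ids)
    ]
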