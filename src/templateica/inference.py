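"""Subject-level inference: t-maps, Bayesian engagement, WTA parcellation.

t-statistic maps are the elementwise ratio of posterior mean to posterior
(marginal) SD. The engagement test declares a vertex engaged by an IC when
the Gaussian posterior probability that the IC value is at or below the
threshold ``gamma`` falls under a Bonferroni-corrected level. Winner-takes-
all parcellation assigns each in-mask vertex the IC with the highest
t-score there.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import EngagementResult, ParcellationMap, SubjectPosterior

__all__ = [
    "t_maps",
    "engagement_test",
    "wta_parcellation",
    "group_parcellation",
]


def t_maps(posterior: SubjectPosterior, on_zero_sd: str = "raise") -> np.ndarray:
    """Posterior mean over posterior SD, per IC and vertex.

    ``on_zero_sd`` controls vertices with zero posterior SD (prior variance
    clamped to zero there): ``"raise"`` reports them as an error, ``"nan"``
    marks them NaN.
    """
    sd = posterior.post_sd
    zero = sd == 0
    if np.any(zero):
        if on_zero_sd == "raise":
            bad = np.argwhere(zero)
            raise ZeroDivisionError(
                f"zero posterior SD at {bad.shape[0]} (IC, vertex) pairs, "
                f"first {bad[:5].tolist()}"
            )
        out = np.full_like(posterior.post_mean, np.nan)
        np.divide(posterior.post_mean, sd, out=out, where=~zero)
        return out
    return posterior.post_mean / sd


def engagement_test(
    posterior: SubjectPosterior,
    gamma: float = 0.0,
    alpha: float = 0.05,
    analysis_mask: np.ndarray | None = None,
) -> EngagementResult:
    """One-sided Bayesian engagement test with Bonferroni correction.

    Per IC and in-mask vertex, the posterior tail probability
    ``P(s <= gamma)`` is computed from the Gaussian posterior; the vertex
    is engaged when that probability is at most ``alpha / m`` with
    ``m`` the number of in-mask vertices (per-IC family). Vertices with
    zero posterior SD are engaged iff their (degenerate) posterior mean
    exceeds gamma with tail probability 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    mean, sd = posterior.post_mean, posterior.post_sd
    Q, V = mean.shape
    if analysis_mask is None:
        analysis_mask = np.ones(V, dtype=bool)
    m = int(analysis_mask.sum())

    p = np.empty_like(mean)
    pos = sd > 0
    p[pos] = stats.norm.cdf((gamma - mean[pos]) / sd[pos])
    p[~pos] = np.where(mean[~pos] > gamma, 0.0, 1.0)
    mask = (p <= alpha / m) & analysis_mask[None, :]
    return EngagementResult(
        t_map=t_maps(posterior, on_zero_sd="nan"),
        p_map=p,
        mask=mask,
        alpha=alpha,
        gamma=gamma,
    )


def _wta(score_maps: np.ndarray, analysis_mask: np.ndarray, source: str) -> ParcellationMap:
    score_maps = np.asarray(score_maps, dtype=float)
    if score_maps.shape[0] < 2:
        raise ValueError("need at least 2 ICs for a parcellation")
    safe = np.where(np.isnan(score_maps), -np.inf, score_maps)
    labels = np.argmax(safe, axis=0) + 1  # argmax breaks ties at lowest index
    labels[~analysis_mask] = 0
    return ParcellationMap(labels=labels, source=source)


def wta_parcellation(
    t_map: np.ndarray,
    analysis_mask: np.ndarray,
    source: str = "subject",
) -> ParcellationMap:
    """Label each in-mask vertex with the IC of the highest t-score.

    Ties go to the lowest IC index; out-of-mask vertices get label 0; NaN
    scores never win.
    """
    return _wta(t_map, analysis_mask, source)


def group_parcellation(
    group_z: np.ndarray, analysis_mask: np.ndarray
) -> ParcellationMap:
    """WTA parcellation of the group-level z-score maps."""
    return _wta(group_z, analysis_mask, "group")
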