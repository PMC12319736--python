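"""Cohort-level analyses over subject posteriors.

Covers area-weighted within-network connectivity strength, partial
Spearman rank correlation of strength with age (controlling for sex and
motion), the per-IC age-association table, and vertex-wise frequency maps
of parcellation agreement.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import CohortRecord, FrequencyMap, ParcellationMap

__all__ = [
    "connectivity_strength",
    "partial_spearman",
    "age_association_table",
    "frequency_map",
]


def connectivity_strength(
    t_map: np.ndarray, mask: np.ndarray, vertex_area: np.ndarray
) -> np.ndarray:
    """Area-weighted mean t-score within each IC's engagement mask.

    ICs with an empty mask get NaN (flagged-undefined, with a warning),
    never a silent zero.
    """
    t_map = np.asarray(t_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    area = np.asarray(vertex_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("vertex areas must be positive")
    Q = t_map.shape[0]
    strength = np.full(Q, np.nan)
    for q in range(Q):
        w = area[mask[q]]
        if w.size == 0:
            warnings.warn(f"IC {q + 1}: empty engagement mask, strength undefined")
            continue
        strength[q] = np.average(t_map[q, mask[q]], weights=w)
    return strength


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Spearman rank correlation of x and y given covariates.

    Both variables are ranked (average ranks for ties), the rank vectors
    are residualized on an intercept plus the covariate columns by OLS,
    and rho is the Pearson correlation of the residuals. The two-sided
    p-value uses the t approximation with N - 2 - K degrees of freedom.
    With no covariates this reduces to classical Spearman's rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    k = covariates.shape[1]
    if n < k + 4:
        raise ValueError(f"need at least K + 4 = {k + 4} observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(covariates))):
        raise ValueError("inputs contain missing or non-finite values")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(n), covariates])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    sx, sy = np.linalg.norm(ex), np.linalg.norm(ey)
    if sx == 0 or sy == 0:
        warnings.warn("constant ranks after residualization; rho undefined")
        return float("nan"), float("nan")
    rho = float(ex @ ey / (sx * sy))
    df = n - 2 - k
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        return rho_c, 0.0
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def age_association_table(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Per-IC partial Spearman correlation of strength with age.

    Covariates are sex and motion. Rows with undefined strength for an IC
    are dropped listwise for that IC (count reported in column ``n``).
    Returns a table with columns ic, rho, p_uncorrected, p_bonferroni, n;
    the Bonferroni correction is across ICs.
    """
    complete = [r for r in cohort]
    if len(complete) < 10:
        raise ValueError("need at least 10 cohort records")
    ages = np.array([r.age_pma_weeks for r in complete])
    covs = np.column_stack(
        [[r.sex for r in complete], [r.motion for r in complete]]
    ).astype(float)
    strengths = np.vstack([r.strength for r in complete])  # N x Q
    Q = strengths.shape[1]
    k = covs.shape[1]

    rows = []
    for q in range(Q):
        ok = np.isfinite(strengths[:, q])
        n_ok = int(ok.sum())
        if n_ok < k + 4:
            warnings.warn(f"IC {q + 1}: only {n_ok} defined strengths, skipped")
            rho, p = float("nan"), float("nan")
        else:
            rho, p = partial_spearman(ages[ok], strengths[ok, q], covs[ok])
        rows.append({"ic": q + 1, "rho": rho, "p_uncorrected": p, "n": n_ok})
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = np.minimum(table["p_uncorrected"] * Q, 1.0)
    return table[["ic", "rho", "p_uncorrected", "p_bonferroni", "n"]]


def frequency_map(parcellations: list[ParcellationMap]) -> FrequencyMap:
    """Modal parcellation label per vertex and the percentage sharing it.

    Modal ties are broken by the lowest label index.
    """
    if not parcellations:
        raise ValueError("need at least one parcellation")
    labels = np.vstack([p.labels for p in parcellations])  # N x V
    n, v = labels.shape
    max_label = int(labels.max())
    counts = np.zeros((max_label + 1, v), dtype=int)
    for lab in range(max_label + 1):
        counts[lab] = (labels == lab).sum(axis=0)
    dominant = np.argmax(counts, axis=0)  # ties -> lowest label
    pct = 100.0 * counts[dominant, np.arange(v)] / n
    return FrequencyMap(dominant_label=dominant, dominant_pct=pct)
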