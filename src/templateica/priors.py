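"""Empirical population prior (template) estimation.

The template consists of, per IC and vertex, the population mean map and
the between-subject variance. Both are estimated from noisy dual-regression
point estimates computed on two pseudo-sessions (contiguous halves) of each
subject's run: the mean is the grand average over subjects and sessions;
the total variance (session-averaged across-subject variance) is decomposed
into within-subject variance (half the across-subject variance of the
session difference) and the between-subject remainder, clamped at zero.
"""

from __future__ import annotations

import numpy as np

from .types import BoldRun, GroupMaps, PriorTemplate

__all__ = [
    "dual_regression",
    "split_pseudo_sessions",
    "estimate_template",
]


def dual_regression(
    run: BoldRun, group_maps: GroupMaps, normalize_timecourses: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage least squares back-projection of group maps into one run.

    Stage 1 regresses the group spatial maps against each frame, giving
    subject time courses (T x Q); stage 2 regresses the (variance
    normalized) time courses against each vertex's series, giving subject
    spatial maps (Q x V). Raises if the spatial design is rank deficient,
    naming the offending ICs.
    """
    maps = group_maps.maps
    Q, V = maps.shape
    T = run.n_frames
    if run.n_vertices != V:
        raise ValueError("run and group maps disagree on V")
    if Q >= min(T, V):
        raise ValueError("Q must be smaller than both T and V")

    design = maps.T  # V x Q
    rank = np.linalg.matrix_rank(design)
    if rank < Q:
        norms = np.linalg.norm(design, axis=0)
        bad = [group_maps.ic_labels[q] for q in np.argsort(norms)[: Q - rank]]
        raise np.linalg.LinAlgError(
            f"group-map design is rank deficient (rank {rank} < {Q}); "
            f"suspect ICs: {bad}"
        )
    time_courses, *_ = np.linalg.lstsq(design, run.data.T, rcond=None)
    time_courses = time_courses.T  # T x Q

    tc = time_courses.copy()
    if normalize_timecourses:
        sd = tc.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise np.linalg.LinAlgError("constant stage-1 time course")
        tc = tc / sd
    subject_maps, *_ = np.linalg.lstsq(tc, run.data, rcond=None)
    return time_courses, subject_maps


def split_pseudo_sessions(run: BoldRun) -> tuple[BoldRun, BoldRun]:
    """Split a run into two contiguous halves (floor(T/2) and the rest)."""
    T = run.n_frames
    if T < 4:
        raise ValueError("need at least 4 frames to form two pseudo-sessions")
    half = T // 2
    first = BoldRun(run.data[:half], run.tr_seconds, run.subject_id + "_ses1")
    second = BoldRun(run.data[half:], run.tr_seconds, run.subject_id + "_ses2")
    return first, second


def estimate_template(
    runs: list[BoldRun],
    group_maps: GroupMaps,
    normalize_timecourses: bool = True,
) -> PriorTemplate:
    """Estimate the population prior from a template cohort.

    For each subject, dual regression is run on each pseudo-session half,
    yielding point estimates ``s_ij``. The prior mean is their grand
    average; the between-subject variance is the session-averaged
    across-subject variance minus half the across-subject variance of the
    session difference, clamped at zero (across-subject variances use the
    unbiased n-1 denominator).
    """
    n = len(runs)
    if n < 2:
        raise ValueError("template estimation needs at least 2 subjects")
    Q, V = group_maps.maps.shape
    s = np.empty((n, 2, Q, V))
    for i, run in enumerate(runs):
        for j, half in enumerate(split_pseudo_sessions(run)):
            _, s[i, j] = dual_regression(half, group_maps, normalize_timecourses)

    mu0 = s.mean(axis=(0, 1))
    per_session_var = s.var(axis=0, ddof=1)        # 2 x Q x V
    sigma_tot_sq = per_session_var.mean(axis=0)
    sigma_noise_sq = 0.5 * (s[:, 1] - s[:, 0]).var(axis=0, ddof=1)
    sigma0_sq = np.maximum(sigma_tot_sq - sigma_noise_sq, 0.0)
    return PriorTemplate(
        mu0=mu0,
        sigma0_sq=sigma0_sq,
        sigma_tot_sq=sigma_tot_sq,
        sigma_noise_sq=sigma_noise_sq,
        n_subjects_used=n,
        ic_labels=list(group_maps.ic_labels),
    )
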