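"""EM estimation of subject-level IC maps under the template-ICA model.

Model, per vertex v of one subject's dimension-reduced BOLD data::

    y(v) = A s(v) + e(v),        e(v) ~ N(0, noise_var * I)
    s(v) = mu0(v) + d(v),        d(v) ~ N(0, diag(sigma0_sq(v)))

``mu0`` and ``sigma0_sq`` are the empirical population prior (the
"template"); the mixing matrix ``A`` and the isotropic residual variance
are subject-specific free parameters estimated by EM. Conditional on
(A, noise_var) the vertex-wise posterior of s(v) is Gaussian in closed
form (E-step); the M-step maximizes the expected complete-data
log-likelihood over A and noise_var. The returned posterior mean and
marginal SD maps are the subject-level IC estimates.
"""

from __future__ import annotations

import numpy as np

from .priors import dual_regression
from .types import BoldRun, GroupMaps, PriorTemplate, ReducedData, SubjectPosterior

__all__ = [
    "reduce_dimension",
    "posterior_given_params",
    "em_fit",
    "expected_complete_loglik",
    "fit_subject",
]

DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 100
#: extra retained SVD dimensions beyond Q, headroom for noise estimation
DEFAULT_DIM_MARGIN = 5


def reduce_dimension(
    run: BoldRun, n_components: int, center: bool = True
) -> ReducedData:
    """Project the (centered) T x V data onto its top left singular
    directions, preserving retained variance.

    The reduced data are ``U_k^T Y`` (k x V); the initial residual-variance
    estimate is the discarded singular-value energy averaged over the
    elements of the original data matrix.
    """
    T = run.n_frames
    if n_components >= T:
        raise ValueError("n_components must be smaller than T")
    data = run.data
    if center:
        data = data - data.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    k = n_components
    y = (s[:k, None] * vt[:k])          # == U_k^T Y
    projection = u[:, :k].T
    resid_var0 = float(np.sum(s[k:] ** 2) / data.size)
    return ReducedData(y=y, projection=projection, resid_var0=resid_var0)


def posterior_given_params(
    y_v: np.ndarray,
    A: np.ndarray,
    noise_var: float,
    mu0_v: np.ndarray,
    sigma0_sq_v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian posterior of s at one vertex given (A, noise_var).

    Components with zero prior variance are hard constraints: they are
    fixed at the prior mean and carry zero rows/columns in the returned
    covariance; the remaining components condition on the residual
    ``y - A_fixed mu0_fixed``.
    """
    y_v = np.asarray(y_v, dtype=float)
    A = np.asarray(A, dtype=float)
    mu0_v = np.asarray(mu0_v, dtype=float)
    s0 = np.asarray(sigma0_sq_v, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("sigma0_sq must be non-negative")
    Q = mu0_v.size
    free = s0 > 0
    mean = mu0_v.astype(float).copy()
    cov = np.zeros((Q, Q))
    if not np.any(free):
        return mean, cov
    A_free = A[:, free]
    resid = y_v - A[:, ~free] @ mu0_v[~free]
    prec = np.diag(1.0 / s0[free]) + A_free.T @ A_free / noise_var
    try:
        cov_free = np.linalg.inv(prec)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular combined precision in E-step"
        ) from err
    rhs = mu0_v[free] / s0[free] + A_free.T @ resid / noise_var
    mean[free] = cov_free @ rhs
    cov[np.ix_(free, free)] = cov_free
    return mean, cov


def _e_step(
    y: np.ndarray,
    A: np.ndarray,
    noise_var: float,
    mu0: np.ndarray,
    sigma0_sq: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized posterior moments at every vertex.

    Returns ``(post_mean (Q x V), post_cov (V x Q x Q))``. Vertices where
    some prior variance is clamped at zero fall back to the per-vertex
    constrained solver.
    """
    Q, V = mu0.shape
    all_free = np.all(sigma0_sq > 0, axis=0)
    post_mean = np.empty((Q, V))
    post_cov = np.zeros((V, Q, Q))

    if np.any(all_free):
        cols = np.flatnonzero(all_free)
        G = A.T @ A / noise_var
        prec = np.broadcast_to(G, (cols.size, Q, Q)).copy()
        inv_s0 = 1.0 / sigma0_sq[:, cols]          # Q x Vf
        prec[:, np.arange(Q), np.arange(Q)] += inv_s0.T
        cov = np.linalg.inv(prec)                   # Vf x Q x Q
        rhs = mu0[:, cols] * inv_s0 + (A.T @ y[:, cols]) / noise_var
        post_mean[:, cols] = np.einsum("vqr,rv->qv", cov, rhs)
        post_cov[cols] = cov
    for v in np.flatnonzero(~all_free):
        post_mean[:, v], post_cov[v] = posterior_given_params(
            y[:, v], A, noise_var, mu0[:, v], sigma0_sq[:, v]
        )
    return post_mean, post_cov


def expected_complete_loglik(
    reduced: ReducedData,
    template: PriorTemplate,
    post_mean: np.ndarray,
    post_cov: np.ndarray,
    A: np.ndarray,
    noise_var: float,
) -> float:
    """Expected complete-data log-likelihood (the EM surrogate objective).

    Sum over vertices of the expected Gaussian log-density of y given s
    plus the expected log prior density of s, under the supplied posterior
    moments. Hard-constrained components (zero prior variance) contribute
    through the likelihood term only.
    """
    y = reduced.y
    Tr, V = y.shape
    Q = post_mean.shape[0]
    second = post_cov + np.einsum("qv,rv->vqr", post_mean, post_mean)
    AtA = A.T @ A
    resid_sq = (
        np.sum(y**2)
        - 2.0 * np.sum((A.T @ y) * post_mean)
        + np.einsum("qr,vqr->", AtA, second)
    )
    ll = -0.5 * Tr * V * np.log(2.0 * np.pi * noise_var) - resid_sq / (
        2.0 * noise_var
    )
    s0 = template.sigma0_sq
    free = s0 > 0
    dev_sq = (
        post_cov[:, np.arange(Q), np.arange(Q)].T
        + (post_mean - template.mu0) ** 2
    )
    ll += np.sum(
        -0.5 * np.log(2.0 * np.pi * s0[free]) - dev_sq[free] / (2.0 * s0[free])
    )
    return float(ll)


def _posterior_entropy(post_cov: np.ndarray, sigma0_sq: np.ndarray) -> float:
    """Total differential entropy of the vertex posteriors (free parts)."""
    total = 0.0
    all_free = np.all(sigma0_sq > 0, axis=0)
    cols = np.flatnonzero(all_free)
    if cols.size:
        sign, logdet = np.linalg.slogdet(post_cov[cols])
        q = sigma0_sq.shape[0]
        total += np.sum(0.5 * (logdet + q * np.log(2.0 * np.pi * np.e)))
    for v in np.flatnonzero(~all_free):
        free = sigma0_sq[:, v] > 0
        if not np.any(free):
            continue
        sub = post_cov[v][np.ix_(free, free)]
        sign, logdet = np.linalg.slogdet(sub)
        total += 0.5 * (logdet + free.sum() * np.log(2.0 * np.pi * np.e))
    return float(total)


def em_fit(
    reduced: ReducedData,
    template: PriorTemplate,
    init_mixing: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    subject_id: str = "unknown",
) -> SubjectPosterior:
    """Fit (A, noise_var) by EM and return the posterior IC maps.

    Convergence is declared when the maximum relative change of A (in
    Frobenius norm) and of noise_var falls below ``tol``. ``loglik_trace``
    records the evidence lower bound after each E-step; because the E-step
    posterior is exact it equals the marginal log-likelihood of the current
    parameters and is non-decreasing across iterations. Reaching
    ``max_iter`` returns ``converged=False``; non-finite parameters abort
    with diagnostics.
    """
    y = reduced.y
    Tr, V = y.shape
    mu0, s0 = template.mu0, template.sigma0_sq
    Q = mu0.shape[0]
    A = np.array(init_mixing, dtype=float)
    if A.shape != (Tr, Q):
        raise ValueError(f"init_mixing must be {Tr} x {Q}")
    if np.linalg.matrix_rank(A) < Q:
        raise ValueError("init_mixing must have full column rank")
    data_scale = float(np.mean(y**2))
    noise_var = max(float(reduced.resid_var0), 1e-10 * max(data_scale, 1.0))

    trace: list[float] = []
    converged = False
    n_iter = 0
    post_mean = np.broadcast_to(mu0, (Q, V)).copy()
    post_cov = np.zeros((V, Q, Q))
    for n_iter in range(1, max_iter + 1):
        post_mean, post_cov = _e_step(y, A, noise_var, mu0, s0)
        ecll = expected_complete_loglik(
            reduced, template, post_mean, post_cov, A, noise_var
        )
        trace.append(ecll + _posterior_entropy(post_cov, s0))

        second = post_cov.sum(axis=0) + post_mean @ post_mean.T   # Q x Q
        cross = y @ post_mean.T                                   # Tr x Q
        A_new = np.linalg.solve(second.T, cross.T).T
        resid_sq = (
            np.sum(y**2)
            - 2.0 * np.sum(cross * A_new)
            + np.einsum("qr,qr->", A_new.T @ A_new, second)
        )
        noise_new = resid_sq / (Tr * V)
        if not (np.all(np.isfinite(A_new)) and np.isfinite(noise_new) and noise_new > 0):
            raise RuntimeError(
                f"EM diverged at iteration {n_iter}: "
                f"noise_var={noise_new!r}, |A|={np.abs(A_new).max()!r}"
            )
        rel_a = np.linalg.norm(A_new - A) / max(np.linalg.norm(A), 1e-300)
        rel_v = abs(noise_new - noise_var) / max(noise_var, 1e-300)
        A, noise_var = A_new, noise_new
        if max(rel_a, rel_v) < tol:
            converged = True
            break

    post_mean, post_cov = _e_step(y, A, noise_var, mu0, s0)
    post_sd = np.sqrt(
        np.maximum(post_cov[:, np.arange(Q), np.arange(Q)].T, 0.0)
    )
    return SubjectPosterior(
        post_mean=post_mean,
        post_sd=post_sd,
        mixing=A,
        noise_var=float(noise_var),
        n_iterations=n_iter,
        converged=converged,
        loglik_trace=np.array(trace),
        subject_id=subject_id,
    )


def fit_subject(
    run: BoldRun,
    template: PriorTemplate,
    n_components: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SubjectPosterior:
    """Convenience wrapper: SVD reduction, dual-regression initialization
    of the mixing matrix, then the EM fit.

    The reduced dimension defaults to Q plus a small margin (capped at
    T - 1). The initial mixing matrix is the projection of the subject's
    variance-normalized dual-regression time courses into the reduced
    space (a "rough" estimate that EM refines).
    """
    Q = template.mu0.shape[0]
    if n_components is None:
        n_components = min(Q + DEFAULT_DIM_MARGIN, run.n_frames - 1)
    if n_components < Q:
        raise ValueError("reduced dimension must be at least Q")
    reduced = reduce_dimension(run, n_components)
    tc, _ = dual_regression(
        run, GroupMaps(maps=template.mu0, ic_labels=list(template.ic_labels))
    )
    tc = tc - tc.mean(axis=0)
    sd = tc.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    init = reduced.projection @ (tc / sd)
    return em_fit(
        reduced, template, init, tol=tol, max_iter=max_iter,
        subject_id=run.subject_id,
    )
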