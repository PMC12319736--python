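"""Motion censoring, temporal SNR mapping and surface smoothing.

Implements DVARS-based outlier flagging (frames whose root-mean-squared
frame-to-frame intensity change exceeds 1.5 IQR above the 75th percentile
of the session), selection of the contiguous block with the fewest
outliers, the subject-exclusion rule, the cohort tSNR map in decibels, and
graph-diffusion smoothing of vertex maps.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .types import BoldRun, CensorResult, SurfaceModel, TsnrMap

__all__ = [
    "compute_dvars",
    "flag_outliers",
    "select_block",
    "censor_run",
    "compute_tsnr",
    "tsnr_mask",
    "smooth_surface",
]

#: 10-minute contiguous block at the reference neonatal acquisition rate
DEFAULT_BLOCK_LENGTH = 1600
#: a subject is excluded when strictly more than this fraction of the
#: retained block is motion-corrupted
DEFAULT_MAX_OUTLIER_FRACTION = 0.10


def compute_dvars(run: BoldRun) -> np.ndarray:
    """Root-mean-square across vertices of the first temporal difference.

    Frame 0 is assigned 0 by convention (no preceding frame).
    """
    diff = np.diff(run.data, axis=0)
    dvars = np.empty(run.n_frames)
    dvars[0] = 0.0
    dvars[1:] = np.sqrt(np.mean(diff**2, axis=1))
    return dvars


def flag_outliers(dvars: np.ndarray, iqr_factor: float = 1.5) -> np.ndarray:
    """Flag frames whose DVARS exceeds Q75 + 1.5 IQR of the session.

    The threshold is computed over the whole session's DVARS values with
    linear-interpolation quantiles; the comparison is strict, so a
    degenerate all-equal series yields no flags.
    """
    dvars = np.asarray(dvars, dtype=float)
    if dvars.size < 4:
        raise ValueError("need at least 4 frames to estimate the IQR")
    q25, q75 = np.percentile(dvars, [25, 75])
    threshold = q75 + iqr_factor * (q75 - q25)
    return dvars > threshold


def select_block(
    flags: np.ndarray,
    block_length: int = DEFAULT_BLOCK_LENGTH,
    max_outlier_fraction: float = DEFAULT_MAX_OUTLIER_FRACTION,
) -> tuple[int, int, bool]:
    """Pick the contiguous window with the fewest flagged frames.

    Returns ``(block_start, outliers_in_block, included)``. Ties are broken
    by the earliest start. The subject is included unless strictly more
    than ``floor(max_outlier_fraction * block_length)`` in-block frames are
    flagged (e.g. more than 160 of 1600 at the default 10%).
    """
    flags = np.asarray(flags, dtype=bool)
    T = flags.size
    if block_length > T:
        raise ValueError(f"block_length {block_length} exceeds run length {T}")
    csum = np.concatenate([[0], np.cumsum(flags)])
    window_counts = csum[block_length:] - csum[:-block_length]
    block_start = int(np.argmin(window_counts))  # argmin takes earliest tie
    outliers_in_block = int(window_counts[block_start])
    allowed = int(np.floor(max_outlier_fraction * block_length))
    included = outliers_in_block <= allowed
    return block_start, outliers_in_block, included


def censor_run(
    run: BoldRun,
    block_length: int = DEFAULT_BLOCK_LENGTH,
    max_outlier_fraction: float = DEFAULT_MAX_OUTLIER_FRACTION,
) -> CensorResult:
    """Full censoring pass: DVARS, outlier flags, block choice, inclusion."""
    dvars = compute_dvars(run)
    flags = flag_outliers(dvars)
    start, n_out, included = select_block(flags, block_length, max_outlier_fraction)
    return CensorResult(
        dvars=dvars,
        outlier_flags=flags,
        block_start=start,
        block_length=block_length,
        outliers_in_block=n_out,
        included=included,
    )


def compute_tsnr(runs: list[BoldRun]) -> TsnrMap:
    """Cohort temporal SNR map in decibels.

    Per subject and vertex, SNR is |temporal mean| / temporal SD; the
    global map is 10*log10 of the across-subject arithmetic mean of the
    linear SNRs. Vertices with zero temporal SD in some subject are NaN in
    that subject's map (and excluded from the mean there); they are
    reported, not silently dropped.
    """
    if not runs:
        raise ValueError("need at least one run")
    V = runs[0].n_vertices
    snr = np.full((len(runs), V), np.nan)
    for i, run in enumerate(runs):
        if run.n_vertices != V:
            raise ValueError("runs disagree on the number of vertices")
        mean = run.data.mean(axis=0)
        sd = run.data.std(axis=0, ddof=0)
        ok = sd > 0
        snr[i, ok] = np.abs(mean[ok]) / sd[ok]
    defined = np.isfinite(snr)
    counts = defined.sum(axis=0)
    sums = np.where(defined, snr, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_snr = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        global_db = 10.0 * np.log10(mean_snr)
    return TsnrMap(per_subject_snr=snr, global_db=global_db)


def tsnr_mask(tsnr: TsnrMap, threshold_db: float = 17.0) -> np.ndarray:
    """Boolean vertex mask of adequate temporal SNR (optional exclusion or
    display mask; undefined vertices are masked out)."""
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(tsnr.global_db),
                        tsnr.global_db > threshold_db, False)


def _mean_edge_length(mesh: SurfaceModel) -> float:
    adj = sp.triu(mesh.adjacency.tocoo())
    if mesh.coords is None:
        return 1.0
    return float(
        np.mean(np.linalg.norm(mesh.coords[adj.row] - mesh.coords[adj.col], axis=1))
    )


def smooth_surface(
    values: np.ndarray, mesh: SurfaceModel, fwhm_mm: float
) -> np.ndarray:
    """Diffusion smoothing on the mesh graph approximating a geodesic
    Gaussian kernel of the requested FWHM.

    The smoothing operator ``S = I - tau * L`` (combinatorial graph
    Laplacian ``L``) is applied repeatedly; it preserves the total map sum
    exactly, keeps non-negative inputs non-negative, and fixes constants.
    The step count is calibrated so the accumulated random-walk variance
    matches ``sigma^2 = fwhm^2 / (8 ln 2)`` in mesh distance units. An
    FWHM below one edge length returns the input unchanged. Vertices
    outside the analysis mask are excluded; disconnected mask components
    are smoothed independently (diffusion cannot cross the mask boundary).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    values = np.asarray(values, dtype=float)
    mask = mesh.analysis_mask
    h = _mean_edge_length(mesh)
    sigma = fwhm_mm / np.sqrt(8.0 * np.log(2.0))
    if fwhm_mm < h:
        return values.copy()

    idx = np.flatnonzero(mask)
    sub = mesh.adjacency[np.ix_(idx, idx)].tocsr()
    sub.data[:] = 1.0
    deg = np.asarray(sub.sum(axis=1)).ravel()
    d_max = deg.max() if deg.size else 1.0
    tau = 0.5 / max(d_max, 1.0)
    lap = sp.diags(deg) - sub
    # per-step squared displacement ~ tau * deg * h^2; 2D surface => sigma^2
    # per coordinate is half the total squared displacement
    step_var = tau * deg.mean() * h**2 / 2.0
    n_steps = max(1, int(np.ceil(sigma**2 / step_var)))

    x = values[idx].copy()
    for _ in range(n_steps):
        x = x - tau * (lap @ x)
    out = values.copy()
    out[idx] = x
    return out


def _mask_components(mesh: SurfaceModel) -> np.ndarray:
    """Connected-component labels of the masked subgraph (diagnostic)."""
    idx = np.flatnonzero(mesh.analysis_mask)
    sub = mesh.adjacency[np.ix_(idx, idx)]
    _, labels = connected_components(sub, directed=False)
    out = np.full(mesh.n_vertices, -1)
    out[idx] = labels
    return out
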