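"""Synthetic surface BOLD cohorts with known ground truth.

The generator reproduces the statistical structure assumed by the
hierarchical template-ICA model: spatially smooth group IC maps on a mesh,
per-subject Gaussian spatial deviations with vertex-wise variance,
per-subject mixing time courses, i.i.d. Gaussian residual noise, additive
motion spikes that drive a DVARS trace, and a monotone age effect on
within-network signal amplitude. Every function is a pure function of its
arguments and seed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import ConvexHull

from .types import BoldRun, SurfaceModel, SyntheticTruth

__all__ = [
    "make_mesh",
    "sample_truth",
    "render_bold",
    "sample_corrupt_frames",
    "dominant_ic_map",
]

#: default amplitude of a group IC map at its blob core, arbitrary BOLD units
GROUP_AMPLITUDE = 3.0
#: subject deviation SD as a fraction of the local group-map magnitude
DEV_SCALE = 0.3
#: additive floor on the deviation SD so between_var > 0 everywhere
DEV_FLOOR = 0.05
#: postmenstrual age range of the emulated cohort, weeks
AGE_RANGE = (37.0, 45.0)
#: reference age at which the amplitude factor equals 1
AGE_CENTER = 41.0


def make_mesh(
    n_vertices: int,
    kind: str = "sphere",
    seed: int = 0,
    radius_mm: float = 50.0,
) -> SurfaceModel:
    """Build a connected surface mesh with positive vertex areas.

    ``kind="grid"`` gives a square 4-neighbour lattice with 1 mm spacing
    (n_vertices must be a perfect square); ``kind="sphere"`` triangulates a
    jittered Fibonacci point set on a sphere of the given radius, a stand-in
    for a registered cortical atlas surface.
    """
    if n_vertices < 16:
        raise ValueError(f"need at least 16 vertices, got {n_vertices}")
    rng = np.random.default_rng(seed)
    if kind == "grid":
        side = int(round(np.sqrt(n_vertices)))
        if side * side != n_vertices:
            raise ValueError("grid meshes require a perfect-square vertex count")
        ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        coords = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
        rows, cols = [], []
        idx = np.arange(n_vertices).reshape(side, side)
        rows.extend(idx[:-1, :].ravel()); cols.extend(idx[1:, :].ravel())
        rows.extend(idx[:, :-1].ravel()); cols.extend(idx[:, 1:].ravel())
        rows, cols = np.array(rows), np.array(cols)
        adjacency = sp.coo_matrix(
            (np.ones(rows.size * 2), (np.r_[rows, cols], np.r_[cols, rows])),
            shape=(n_vertices, n_vertices),
        ).tocsr()
        vertex_area = np.ones(n_vertices)
    elif kind in ("sphere", "sphere-like"):
        # Fibonacci lattice with a small jitter so triangulations differ by seed
        k = np.arange(n_vertices)
        phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n_vertices)
        golden = np.pi * (1.0 + np.sqrt(5.0))
        theta = golden * k + rng.uniform(0, 2 * np.pi)
        pts = np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        pts += rng.normal(scale=1e-3, size=pts.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        coords = pts * radius_mm
        hull = ConvexHull(coords)
        tri = hull.simplices
        edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
        adjacency = sp.coo_matrix(
            (
                np.ones(edges.shape[0] * 2),
                (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]]),
            ),
            shape=(n_vertices, n_vertices),
        ).tocsr()
        adjacency.data[:] = 1.0
        # one third of each incident triangle's area per vertex
        a = coords[tri[:, 0]]
        cross = np.cross(coords[tri[:, 1]] - a, coords[tri[:, 2]] - a)
        tri_area = 0.5 * np.linalg.norm(cross, axis=1)
        vertex_area = np.zeros(n_vertices)
        for c in range(3):
            np.add.at(vertex_area, tri[:, c], tri_area / 3.0)
    else:
        raise ValueError(f"unknown mesh kind {kind!r}")

    n_comp, _ = connected_components(adjacency, directed=False)
    if n_comp != 1:
        raise RuntimeError("generated mesh is not connected")
    return SurfaceModel(
        n_vertices=n_vertices,
        adjacency=adjacency,
        vertex_area=vertex_area,
        analysis_mask=np.ones(n_vertices, dtype=bool),
        coords=coords,
    )


def _edge_weighted_graph(mesh: SurfaceModel) -> sp.csr_matrix:
    """Adjacency with Euclidean edge lengths as weights (for geodesics)."""
    adj = mesh.adjacency.tocoo()
    if mesh.coords is None:
        w = np.ones(adj.data.size)
    else:
        w = np.linalg.norm(mesh.coords[adj.row] - mesh.coords[adj.col], axis=1)
    return sp.csr_matrix((w, (adj.row, adj.col)), shape=adj.shape)


def _farthest_point_centers(graph: sp.csr_matrix, n_centers: int, rng) -> np.ndarray:
    """Greedy farthest-point sampling of blob centers on the mesh graph."""
    n = graph.shape[0]
    centers = [int(rng.integers(n))]
    dist = dijkstra(graph, indices=centers[0], directed=False)
    for _ in range(n_centers - 1):
        nxt = int(np.argmax(dist))
        centers.append(nxt)
        dist = np.minimum(dist, dijkstra(graph, indices=nxt, directed=False))
    return np.array(centers)


def _group_blob_maps(mesh: SurfaceModel, n_ics: int, rng) -> np.ndarray:
    """Geodesic Gaussian bumps at mutually distant centers (Q x V)."""
    graph = _edge_weighted_graph(mesh)
    centers = _farthest_point_centers(graph, n_ics, rng)
    d = dijkstra(graph, indices=centers, directed=False)  # Q x V
    # blob width scaled so the Q blobs tile the mesh with limited overlap
    typical_sep = np.median(np.partition(d[:, centers], 1, axis=1)[:, 1])
    sigma = typical_sep / 3.0
    maps = GROUP_AMPLITUDE * np.exp(-0.5 * (d / sigma) ** 2)
    return maps


def sample_truth(
    mesh: SurfaceModel,
    n_subjects: int,
    n_ics: int,
    n_timepoints: int,
    noise_sd: float = 1.0,
    age_effect: float = 0.0,
    seed: int = 0,
    dev_scale: float = DEV_SCALE,
    dev_floor: float = DEV_FLOOR,
    dev_smooth_sigma: float = 0.0,
    tr_seconds: float = 0.392,
) -> SyntheticTruth:
    """Draw cohort-level ground truth under the hierarchical model.

    Group maps are geodesic Gaussian blobs with limited mutual overlap.
    Subject maps are the group maps plus vertex-independent Gaussian
    deviations whose SD is ``dev_scale`` times the local group-map magnitude
    plus the floor ``dev_floor`` (set both to 0 for a degenerate cohort with
    no between-subject variability; ``dev_smooth_sigma > 0`` optionally smooths the
    deviation field along the mesh, off by default since the model assumes
    vertex-independent deviations). Mixing time courses are smoothed,
    orthogonalized, unit-variance Gaussian processes; subject i's columns are
    scaled by the amplitude factor ``1 + age_effect * (age_i - 41)`` so
    within-network signal amplitude grows monotonically with age.
    """
    if n_ics < 2:
        raise ValueError("need at least 2 ICs")
    if n_timepoints <= n_ics:
        raise ValueError("n_timepoints must exceed n_ics")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)

    group_maps = _group_blob_maps(mesh, n_ics, rng)
    between_sd = dev_scale * np.abs(group_maps) + dev_floor
    between_var = between_sd**2

    V = mesh.n_vertices
    deviations = rng.normal(size=(n_subjects, n_ics, V)) * between_sd
    if dev_smooth_sigma > 0:
        from .censor_qc import smooth_surface

        for i in range(n_subjects):
            for q in range(n_ics):
                raw = smooth_surface(deviations[i, q], mesh, dev_smooth_sigma)
                # re-standardize so the target vertex-wise variance is kept
                raw_sd = raw.std()
                if raw_sd > 0:
                    deviations[i, q] = raw / raw_sd * between_sd[q].mean()
    subject_maps = group_maps[None] + deviations

    ages = rng.uniform(*AGE_RANGE, size=n_subjects)
    sexes = rng.integers(0, 2, size=n_subjects)
    motion_levels = rng.uniform(0.0, 0.08, size=n_subjects)
    amplitude = 1.0 + age_effect * (ages - AGE_CENTER)
    if np.any(amplitude <= 0):
        raise ValueError("age_effect too large: non-positive amplitude factor")

    mixing = np.empty((n_subjects, n_timepoints, n_ics))
    for i in range(n_subjects):
        tc = rng.normal(size=(n_timepoints, n_ics))
        tc = gaussian_filter1d(tc, sigma=2.0, axis=0)
        tc, _ = np.linalg.qr(tc - tc.mean(axis=0))
        tc /= tc.std(axis=0, ddof=0)  # unit variance before age scaling
        mixing[i] = tc * amplitude[i]

    return SyntheticTruth(
        mesh=mesh,
        group_maps=group_maps,
        between_var=between_var,
        subject_maps=subject_maps,
        mixing=mixing,
        noise_var=noise_sd**2,
        ages=ages,
        sexes=sexes,
        motion_levels=motion_levels,
        age_effect=age_effect,
        tr_seconds=tr_seconds,
        seed=seed,
    )


def render_bold(
    truth: SyntheticTruth,
    subject: int,
    corrupt_frames: np.ndarray | None = None,
    seed: int | None = None,
    spike_scale: float = 2.5,
) -> BoldRun:
    """Render one subject's T x V BOLD run: mixing @ maps + Gaussian noise.

    Frames listed in ``corrupt_frames`` receive a global intensity jump
    (random sign, magnitude ``spike_scale`` times the clean-data RMS) large
    enough that isolated corrupted frames exceed the session-relative DVARS
    outlier threshold of the censoring stage, yet mild enough that the few
    corrupted frames tolerated inside a retained block do not dominate the
    fit — emulating residual in-scanner motion after block censoring. ``seed`` defaults to a subject-specific value
    derived from the truth seed, so repeated calls are identical.
    """
    n = truth.n_subjects
    if not 0 <= subject < n:
        raise IndexError(f"subject index {subject} out of range [0, {n})")
    T = truth.n_timepoints
    if corrupt_frames is None:
        corrupt_frames = np.empty(0, dtype=int)
    corrupt_frames = np.asarray(corrupt_frames, dtype=int)
    if corrupt_frames.size and (
        corrupt_frames.min() < 0 or corrupt_frames.max() >= T
    ):
        raise ValueError("corrupt_frames outside [0, T)")
    if seed is None:
        seed = (truth.seed * 100003 + 7919 * (subject + 1)) % (2**31)
    rng = np.random.default_rng(seed)

    clean = truth.mixing[subject] @ truth.subject_maps[subject]
    data = clean + rng.normal(
        scale=np.sqrt(truth.noise_var), size=clean.shape
    )
    if corrupt_frames.size:
        rms = np.sqrt(np.mean(clean**2)) + np.sqrt(truth.noise_var)
        signs = rng.choice([-1.0, 1.0], size=corrupt_frames.size)
        jitter = 1.0 + 0.25 * rng.random(corrupt_frames.size)
        data[corrupt_frames] += (spike_scale * rms * signs * jitter)[:, None]
    return BoldRun(
        data=data, tr_seconds=truth.tr_seconds, subject_id=f"sub-{subject:03d}"
    )


def sample_corrupt_frames(
    truth: SyntheticTruth, subject: int, seed: int | None = None,
    mean_burst: float = 4.0,
) -> np.ndarray:
    """Draw motion-corrupted frame bursts at the subject's motion level.

    Burst onsets are uniform, burst lengths geometric with the given mean,
    and the total corrupted fraction targets ``motion_levels[subject]``.
    """
    if seed is None:
        seed = (truth.seed * 99991 + 104729 * (subject + 1)) % (2**31)
    rng = np.random.default_rng(seed)
    T = truth.n_timepoints
    target = int(round(truth.motion_levels[subject] * T))
    frames: set[int] = set()
    while len(frames) < target:
        start = int(rng.integers(T))
        length = 1 + rng.geometric(1.0 / mean_burst)
        frames.update(range(start, min(start + length, T)))
    return np.array(sorted(frames), dtype=int)[:target] if frames else np.empty(0, int)


def dominant_ic_map(truth: SyntheticTruth) -> np.ndarray:
    """Per-vertex index (1-based) of the group IC with the largest value."""
    return np.argmax(truth.group_maps, axis=0) + 1
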