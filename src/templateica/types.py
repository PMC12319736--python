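"""Shared data containers for the surface-based template-ICA pipeline.

All spatial quantities live on a cortical surface mesh with ``V`` vertices;
``Q`` denotes the number of independent components (one per resting-state
network), ``T`` the number of BOLD frames and ``N`` the number of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SurfaceModel",
    "BoldRun",
    "SyntheticTruth",
    "GroupMaps",
    "PriorTemplate",
    "ReducedData",
    "SubjectPosterior",
    "CensorResult",
    "TsnrMap",
    "EngagementResult",
    "ParcellationMap",
    "CohortRecord",
    "FrequencyMap",
]


@dataclass
class SurfaceModel:
    """Cortical surface mesh geometry used for all vertex-wise analyses.

    Parameters
    ----------
    n_vertices
        Number of mesh vertices ``V``.
    adjacency
        Symmetric, irreflexive sparse vertex-vertex neighbour matrix (V x V).
    vertex_area
        Midthickness vertex area in mm^2, strictly positive (V,).
    analysis_mask
        Boolean per vertex; False marks excluded vertices (medial wall,
        low-tSNR regions).
    coords
        Optional vertex coordinates in mm (V x 3 or V x 2), used for
        geodesic-distance computations.
    """

    n_vertices: int
    adjacency: sp.spmatrix
    vertex_area: np.ndarray
    analysis_mask: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertex_area = np.asarray(self.vertex_area, dtype=float)
        self.analysis_mask = np.asarray(self.analysis_mask, dtype=bool)
        if self.vertex_area.shape != (self.n_vertices,):
            raise ValueError("vertex_area must have shape (n_vertices,)")
        if np.any(self.vertex_area <= 0):
            raise ValueError("vertex areas must be strictly positive")
        if self.analysis_mask.shape != (self.n_vertices,):
            raise ValueError("analysis_mask must have shape (n_vertices,)")

    @property
    def total_area(self) -> float:
        return float(self.vertex_area.sum())


@dataclass
class BoldRun:
    """One subject's vertex-wise BOLD time series (T frames x V vertices)."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("BOLD data must be a T x V matrix with T >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort under the hierarchical model.

    Subject maps are group maps plus vertex-independent Gaussian deviations
    with variance ``between_var``; BOLD data are mixed through per-subject
    time courses whose amplitude scales monotonically with age.
    """

    mesh: SurfaceModel
    group_maps: np.ndarray       # Q x V, true population mean maps
    between_var: np.ndarray      # Q x V, true between-subject variance
    subject_maps: np.ndarray     # N x Q x V, true subject-level IC maps
    mixing: np.ndarray           # N x T x Q, true mixing time courses
    noise_var: float             # residual Gaussian noise variance
    ages: np.ndarray             # N, weeks postmenstrual age
    sexes: np.ndarray            # N, binary codes
    motion_levels: np.ndarray    # N, expected corrupt-frame fraction
    age_effect: float
    tr_seconds: float
    seed: int

    @property
    def n_subjects(self) -> int:
        return self.subject_maps.shape[0]

    @property
    def n_ics(self) -> int:
        return self.group_maps.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.mixing.shape[1]


@dataclass
class GroupMaps:
    """Group-level spatial IC maps (the output of a group decomposition)."""

    maps: np.ndarray             # Q x V
    ic_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 2:
            raise ValueError("group maps must be a Q x V matrix with Q >= 2")
        if np.any(np.all(self.maps == 0, axis=1)):
            raise ValueError("group maps contain an identically-zero row")
        if not self.ic_labels:
            self.ic_labels = [f"IC{q + 1}" for q in range(self.maps.shape[0])]

    @property
    def n_ics(self) -> int:
        return self.maps.shape[0]


@dataclass
class PriorTemplate:
    """Empirical population prior: mean and between-subject variance per IC.

    ``sigma0_sq`` is the between-subject variance obtained by subtracting the
    within-subject (pseudo-session noise) variance from the total variance,
    clamped at zero.
    """

    mu0: np.ndarray              # Q x V
    sigma0_sq: np.ndarray        # Q x V, >= 0
    sigma_tot_sq: np.ndarray     # Q x V
    sigma_noise_sq: np.ndarray   # Q x V
    n_subjects_used: int
    ic_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.sigma0_sq < 0):
            raise ValueError("sigma0_sq must be non-negative")


@dataclass
class ReducedData:
    """SVD-reduced BOLD data for one subject (Tr x V) with its projection."""

    y: np.ndarray                # Tr x V
    projection: np.ndarray       # Tr x T, orthonormal rows
    resid_var0: float            # initial residual-variance estimate

    @property
    def n_components(self) -> int:
        return self.y.shape[0]


@dataclass
class SubjectPosterior:
    """Posterior summary of one subject's IC maps after the EM fit."""

    post_mean: np.ndarray        # Q x V
    post_sd: np.ndarray          # Q x V, > 0 where sigma0_sq > 0
    mixing: np.ndarray           # Tr x Q
    noise_var: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray
    subject_id: str = "unknown"


@dataclass
class CensorResult:
    """Outcome of DVARS-based contiguous block censoring for one run."""

    dvars: np.ndarray
    outlier_flags: np.ndarray
    block_start: int
    block_length: int
    outliers_in_block: int
    included: bool


@dataclass
class TsnrMap:
    """Per-subject temporal SNR (linear) and the cohort map in decibels."""

    per_subject_snr: np.ndarray  # N x V, NaN where temporal SD is zero
    global_db: np.ndarray        # V, decibels; NaN where undefined


@dataclass
class EngagementResult:
    """Vertex-wise Bayesian engagement test output for one subject."""

    t_map: np.ndarray            # Q x V
    p_map: np.ndarray            # Q x V posterior tail probabilities
    mask: np.ndarray             # Q x V booleans
    alpha: float
    gamma: float
    correction: str = "bonferroni"


@dataclass
class ParcellationMap:
    """Winner-takes-all network labels per vertex (0 = outside mask)."""

    labels: np.ndarray           # V integers in [0..Q]
    source: str


@dataclass
class CohortRecord:
    """One analyzed subject's covariates and per-IC connectivity strengths."""

    subject_id: str
    age_pma_weeks: float
    sex: int
    motion: float
    strength: np.ndarray         # Q reals, NaN where engagement mask empty


@dataclass
class FrequencyMap:
    """Per-vertex modal parcellation label and the percentage sharing it."""

    dominant_label: np.ndarray   # V integers
    dominant_pct: np.ndarray     # V reals in [0, 100]
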