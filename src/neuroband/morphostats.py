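"""Vertex-wise cortical-thickness statistics on a triangulated surface.

Group contrasts are ordinary least squares per vertex of thickness on a
group indicator plus covariates (age, sex, education, MMSE, WMH load), with
a two-sided t-test on the group coefficient.  Supra-threshold vertices
(p < 0.001 uncorrected by default) are grouped into sign-consistent
connected clusters; clusters smaller than a minimum extent (30 mm^2 for
group contrasts, 15 mm^2 for correlation maps) are discarded.  Cluster
extent is the sum of member vertex areas, and the total atrophy extent of a
contrast is the sum of its cluster extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

DEFAULT_P_THRESHOLD = 0.001
DEFAULT_MIN_AREA_GROUP = 30.0  # mm^2
DEFAULT_MIN_AREA_CORRELATION = 15.0  # mm^2
DEFAULT_COVARIATES = ("age", "sex", "education", "mmse", "wmh_volume")


@dataclass
class Surface:
    """A surface mesh reduced to per-vertex areas and an adjacency structure."""

    vertex_area: np.ndarray
    neighbors: list[np.ndarray]

    def __post_init__(self) -> None:
        self.vertex_area = np.asarray(self.vertex_area, dtype=float)
        if np.any(self.vertex_area <= 0):
            raise ValueError("vertex areas must be positive")
        if len(self.neighbors) != self.n_vertices:
            raise ValueError("one neighbor list per vertex required")
        self.neighbors = [np.asarray(nb, dtype=int) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if j < 0 or j >= self.n_vertices:
                    raise ValueError(f"vertex {i} lists out-of-range neighbor {j}")
                if i not in self.neighbors[j]:
                    raise ValueError(f"adjacency not symmetric: {i} -> {j}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_area)

    def adjacency_matrix(self) -> sparse.csr_matrix:
        rows = np.concatenate(
            [np.full(len(nb), i) for i, nb in enumerate(self.neighbors)]
            or [np.empty(0, dtype=int)]
        )
        cols = (
            np.concatenate(self.neighbors)
            if self.neighbors
            else np.empty(0, dtype=int)
        )
        data = np.ones(len(rows), dtype=np.int8)
        n = self.n_vertices
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


@dataclass
class ThicknessDataset:
    """Per-subject thickness on a common surface plus covariates and scores."""

    surface: Surface
    thickness: np.ndarray  # subjects x vertices, mm
    covariates: pd.DataFrame  # per-subject: age, sex, education, mmse, wmh_volume
    groups: np.ndarray  # per-subject label: low/middle/high
    memory_scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        n_subj, n_vert = self.thickness.shape
        if n_vert != self.surface.n_vertices:
            raise ValueError("thickness columns must match surface vertices")
        if len(self.covariates) != n_subj or len(self.groups) != n_subj:
            raise ValueError("covariates and groups must have one row per subject")
        if self.memory_scores is not None and len(self.memory_scores) != n_subj:
            raise ValueError("memory_scores must have one row per subject")

    @property
    def n_subjects(self) -> int:
        return self.thickness.shape[0]


@dataclass
class GlmResult:
    """Per-vertex outcome of the group-contrast GLM."""

    t: np.ndarray
    p: np.ndarray
    coefficient: np.ndarray  # group-coefficient (first group minus second), mm
    df: int
    contrast: tuple[str, str]


@dataclass
class ClusterResult:
    """A sign-consistent connected supra-threshold component."""

    cluster_id: int
    vertices: np.ndarray
    area: float
    peak_vertex: int
    peak_p: float
    direction: str  # "negative" = first group thinner (or negative correlation)
    group_mean_thickness: dict[str, float] = field(default_factory=dict)


def _design_matrix(
    dataset: ThicknessDataset,
    subject_idx: np.ndarray,
    indicator: np.ndarray,
    covariates: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(subject_idx)), indicator.astype(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        cols.append(dataset.covariates.iloc[subject_idx][cov].to_numpy(dtype=float))
        names.append(cov)
    return np.column_stack(cols), names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    culprits = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            culprits.append(names[j])
    return culprits


def vertexwise_glm(
    dataset: ThicknessDataset,
    contrast: tuple[str, str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> GlmResult:
    """OLS of thickness on a group indicator plus covariates, per vertex.

    The indicator codes membership in ``contrast[0]``; a negative coefficient
    therefore means the first-named group is thinner.
    """
    g1, g2 = contrast
    sel = np.flatnonzero((dataset.groups == g1) | (dataset.groups == g2))
    if not (dataset.groups == g1).any() or not (dataset.groups == g2).any():
        raise ValueError(f"both contrast groups must be non-empty: {contrast}")
    indicator = (dataset.groups[sel] == g1).astype(float)
    covariates = [c for c in covariates if c in dataset.covariates.columns]
    X, names = _design_matrix(dataset, sel, indicator, covariates)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            f"design matrix is rank-deficient; collinear columns: "
            f"{_collinear_columns(X, names)}"
        )
    if n <= p:
        raise ValueError(f"{n} subjects cannot support {p} design columns")
    Y = dataset.thickness[sel]
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # p x vertices
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return GlmResult(t=t, p=pvals, coefficient=beta[1], df=df, contrast=(g1, g2))


def extract_clusters(
    p_map: np.ndarray,
    t_map: np.ndarray,
    vertex_area: np.ndarray,
    neighbors: list[np.ndarray] | Surface,
    p_thresh: float = DEFAULT_P_THRESHOLD,
    min_area: float = DEFAULT_MIN_AREA_GROUP,
) -> list[ClusterResult]:
    """Sign-consistent connected supra-threshold components above ``min_area``.

    A vertex is supra-threshold when ``p < p_thresh``.  Components are
    connected sets of supra-threshold vertices sharing the sign of the test
    statistic; extent is the sum of member vertex areas and components with
    extent below ``min_area`` are discarded.  Clusters are returned sorted by
    decreasing extent (ties by lowest member vertex id).
    """
    if isinstance(neighbors, Surface):
        surface = neighbors
    else:
        surface = Surface(vertex_area, list(neighbors))
    p_map = np.asarray(p_map, dtype=float)
    t_map = np.asarray(t_map, dtype=float)
    vertex_area = np.asarray(vertex_area, dtype=float)
    adj = surface.adjacency_matrix()
    clusters: list[ClusterResult] = []
    for sign, direction in ((-1, "negative"), (1, "positive")):
        supra = (p_map < p_thresh) & (np.sign(t_map) == sign)
        idx = np.flatnonzero(supra)
        if len(idx) == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for comp in range(n_comp):
            members = idx[labels == comp]
            area = float(vertex_area[members].sum())
            if area < min_area:
                continue
            peak = members[np.argmin(p_map[members])]
            clusters.append(
                ClusterResult(
                    cluster_id=-1,
                    vertices=members,
                    area=area,
                    peak_vertex=int(peak),
                    peak_p=float(p_map[peak]),
                    direction=direction,
                )
            )
    clusters.sort(key=lambda c: (-c.area, int(c.vertices.min())))
    for i, c in enumerate(clusters):
        c.cluster_id = i + 1
    return clusters


def summarize_clusters(
    dataset: ThicknessDataset,
    clusters: list[ClusterResult],
    groups: Sequence[str],
) -> list[ClusterResult]:
    """Fill per-group mean thickness (mm) over each cluster's vertices."""
    for c in clusters:
        c.group_mean_thickness = {
            g: float(dataset.thickness[np.flatnonzero(dataset.groups == g)][:, c.vertices].mean())
            for g in groups
            if (dataset.groups == g).any()
        }
    return clusters


def total_atrophy_extent(clusters: Sequence[ClusterResult] | Sequence[float]) -> float:
    """Total extent in mm^2: the sum of cluster areas."""
    return float(
        sum(c.area if isinstance(c, ClusterResult) else float(c) for c in clusters)
    )


@dataclass
class CorrelationResult:
    """Per-vertex thickness-score Pearson correlation within one group."""

    r: np.ndarray
    p: np.ndarray
    n: int
    clusters: list[ClusterResult]


def correlation_map(
    dataset: ThicknessDataset,
    score: str | np.ndarray,
    group: str,
    p_thresh: float = DEFAULT_P_THRESHOLD,
    min_area: float = DEFAULT_MIN_AREA_CORRELATION,
) -> CorrelationResult:
    """Pearson correlation of thickness with a memory score within one group."""
    sel = np.flatnonzero(dataset.groups == group)
    if len(sel) < 4:
        raise ValueError(f"group {group!r} has {len(sel)} subjects; need >= 4")
    if isinstance(score, str):
        if dataset.memory_scores is None or score not in dataset.memory_scores:
            raise ValueError(f"memory score {score!r} not present in dataset")
        y = dataset.memory_scores.iloc[sel][score].to_numpy(dtype=float)
    else:
        y = np.asarray(score, dtype=float)[sel]
    if np.isnan(y).any():
        raise ValueError("score missing for some group members")
    if y.std() == 0:
        raise ValueError("zero-variance score")
    T = dataset.thickness[sel]
    n = len(sel)
    yc = y - y.mean()
    Tc = T - T.mean(axis=0)
    denom = np.sqrt((Tc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, Tc.T @ yc / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    clusters = extract_clusters(
        p, r, dataset.surface.vertex_area, dataset.surface, p_thresh, min_area
    )
    return CorrelationResult(r=r, p=p, n=n, clusters=clusters)


def regional_correlation(
    dataset: ThicknessDataset, score: str | np.ndarray, group: str, vertices: np.ndarray
) -> float:
    """Pearson correlation of a score with mean regional thickness in a group."""
    sel = np.flatnonzero(dataset.groups == group)
    if len(sel) < 4:
        raise ValueError(f"group {group!r} has {len(sel)} subjects; need >= 4")
    if isinstance(score, str):
        y = dataset.memory_scores.iloc[sel][score].to_numpy(dtype=float)
    else:
        y = np.asarray(score, dtype=float)[sel]
    regional = dataset.thickness[np.ix_(sel, np.asarray(vertices, dtype=int))].mean(axis=1)
    return float(np.corrcoef(regional, y)[0, 1])


def smooth_thickness(
    surface: Surface, thickness: np.ndarray, n_iter: int = 0, fwhm_mm: float | None = None
) -> np.ndarray:
    """Iterative neighbor-average smoothing of thickness maps.

    Each iteration replaces a vertex value by the mean of itself and its
    neighbors.  When ``fwhm_mm`` is given the iteration count is calibrated
    from the mean inter-vertex spacing (estimated as sqrt(mean vertex area)):
    one iteration contributes roughly spacing^2/2 of squared Gaussian width.
    """
    thickness = np.asarray(thickness, dtype=float)
    if fwhm_mm is not None:
        spacing = float(np.sqrt(surface.vertex_area.mean()))
        sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        n_iter = max(1, int(round(2.0 * (sigma / spacing) ** 2)))
    if n_iter <= 0:
        return thickness.copy()
    adj = surface.adjacency_matrix().astype(float)
    adj = adj + sparse.identity(surface.n_vertices, format="csr")
    weights = np.asarray(adj.sum(axis=1)).ravel()
    out = thickness.copy()
    for _ in range(n_iter):
        out = (adj @ out.T).T / weights
    return out
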