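"""Post-inference analysis of transition-vector fields.

Projection to principal components, inverse-distance-weighted grid
smoothing for display, density-based estimation of basins of attraction,
vector-field comparison metrics (magnitude and angle changes, with a
shuffled null), and edge-sensitivity analysis that re-runs inference on
perturbed network topologies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .core import (
    DEFAULT_MIN_NEIGHBORS,
    EmbeddingSpace,
    TransitionVectors,
    run_sticc,
)
from .grn import GRNTopology, perturb_topology
from .matrix import ExpressionMatrix

__all__ = [
    "ProjectionModel",
    "SmoothedField",
    "SensitivityRecord",
    "pca_project",
    "grid_smooth",
    "estimate_basins",
    "compare_fields",
    "shuffled_null",
    "edge_sensitivity",
]

logger = logging.getLogger(__name__)

_IDW_DELTA = 1e-9


@dataclass
class ProjectionModel:
    """Centered PCA with a deterministic sign convention.

    Loadings are genes × components, orthonormal columns; per-gene centers
    and explained-variance fractions are retained so new data (or vectors,
    which are translation-free) can be projected consistently.
    """

    loadings: np.ndarray
    centers: np.ndarray
    explained_variance_ratio: np.ndarray
    genes: list[str]

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.centers) @ self.loadings

    def transform_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Project direction vectors (no centering)."""
        return np.asarray(vectors, dtype=float) @ self.loadings

    def inverse_transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.loadings.T + self.centers


def pca_project(
    expression: ExpressionMatrix, n_components: int = 2
) -> tuple[ProjectionModel, np.ndarray]:
    """Centered (not scaled) PCA of an expression matrix.

    The sign of each component is fixed so that its largest-|loading|
    entry is positive, making projections reproducible across runs.
    Returns the projection model and the cells × n_components coordinates.
    """
    vals = expression.values()
    max_rank = min(vals.shape[0] - 1, vals.shape[1])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds the data rank bound {max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(vals)
    loadings = pca.components_.T.copy()  # genes × components
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            coords[:, c] *= -1
    model = ProjectionModel(
        loadings=loadings,
        centers=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        genes=expression.genes,
    )
    return model, coords


def embedding_from_pca(
    expression: ExpressionMatrix, n_components: int = 2
) -> tuple[EmbeddingSpace, ProjectionModel]:
    """Convenience: PCA coordinates wrapped as an embedding space."""
    model, coords = pca_project(expression, n_components)
    return (
        EmbeddingSpace(coords, cells=expression.cells, tag=f"pca{n_components}"),
        model,
    )


@dataclass
class SmoothedField:
    """Inverse-distance-weighted vector field on a uniform 2D grid.

    Only nodes with at least one contributing cell inside the influence
    radius carry a vector (``occupied`` mask).
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    vectors: np.ndarray  # (grid², 2), NaN where unoccupied
    occupied: np.ndarray
    n_contributors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid_x,
                "y": self.grid_y,
                "vx": self.vectors[:, 0],
                "vy": self.vectors[:, 1],
                "n_contributors": self.n_contributors,
            }
        )[self.occupied]


def grid_smooth(
    coords2d: np.ndarray,
    vectors: np.ndarray,
    grid_size: int = 20,
    power: float = 2.0,
    influence_radius: float | None = None,
) -> SmoothedField:
    """Smooth per-cell vectors onto a uniform grid for display.

    Each node of a ``grid_size`` × ``grid_size`` lattice over the bounding
    box receives the inverse-distance-weighted mean of the vectors of cells
    within ``influence_radius`` (default: one grid spacing), with weights
    1/(d + δ)^power. Nodes with no cell in range are masked.
    """
    coords2d = np.asarray(coords2d, dtype=float)
    vectors = np.asarray(vectors, dtype=float)
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    ok = np.all(np.isfinite(vectors), axis=1) & np.all(np.isfinite(coords2d), axis=1)
    coords2d, vectors = coords2d[ok], vectors[ok]
    lo = coords2d.min(axis=0)
    hi = coords2d.max(axis=0)
    gx, gy = np.meshgrid(
        np.linspace(lo[0], hi[0], grid_size), np.linspace(lo[1], hi[1], grid_size)
    )
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    if influence_radius is None:
        influence_radius = float(np.max((hi - lo) / (grid_size - 1)))
    d = np.linalg.norm(nodes[:, None, :] - coords2d[None, :, :], axis=2)
    within = d <= influence_radius
    w = np.where(within, 1.0 / (d + _IDW_DELTA) ** power, 0.0)
    wsum = w.sum(axis=1)
    occupied = wsum > 0
    out = np.full((nodes.shape[0], 2), np.nan)
    out[occupied] = (w[occupied] @ vectors) / wsum[occupied, None]
    return SmoothedField(
        grid_x=nodes[:, 0],
        grid_y=nodes[:, 1],
        vectors=out,
        occupied=occupied,
        n_contributors=within.sum(axis=1),
    )


def estimate_basins(
    coords2d: np.ndarray,
    grid_size: int = 100,
    min_density_fraction: float = 0.10,
) -> np.ndarray:
    """Estimate basin-of-attraction centers as 2D density peaks.

    A Gaussian KDE (Scott bandwidth) is evaluated on a ``grid_size``²
    lattice over the bounding box; local maxima over the 8-neighborhood
    are kept if their density exceeds ``min_density_fraction`` of the
    global maximum, which discards spurious peaks far from the visible
    clusters. Returns peak coordinates sorted by descending density.
    """
    pts = np.asarray(coords2d, dtype=float)
    if pts.shape[0] < 50:
        raise ValueError("basin estimation needs at least 50 points")
    try:
        kde = gaussian_kde(pts.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate (collinear) coordinates") from exc
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_size, grid_size)
    # 8-neighborhood local maxima (strictly greater than at least one
    # neighbor, not less than any; ties inside plateaus collapse below).
    from scipy.ndimage import maximum_filter

    local_max = dens == maximum_filter(dens, size=3, mode="nearest")
    local_max &= dens >= min_density_fraction * dens.max()
    iy, ix = np.nonzero(local_max)
    peaks = np.column_stack([xs[ix], ys[iy]])
    order = np.argsort(-dens[iy, ix])
    return peaks[order]


def _component(tv: TransitionVectors, component: str) -> np.ndarray:
    try:
        return {
            "net": tv.net_flow,
            "rev": tv.reversibility,
            "v1": tv.v1,
            "v2": tv.v2,
        }[component]
    except KeyError:
        raise ValueError(f"unknown component {component!r}") from None


def _angles_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute angle in [0, π] between row vectors (first two coords)."""
    a2, b2 = a[:, :2], b[:, :2]
    dot = np.sum(a2 * b2, axis=1)
    na = np.linalg.norm(a2, axis=1)
    nb = np.linalg.norm(b2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dot / (na * nb), -1.0, 1.0)
    return np.arccos(cosang)


def compare_fields(
    a: TransitionVectors, b: TransitionVectors, component: str = "net"
) -> pd.DataFrame:
    """Per-cell change between two vector fields on the same cells.

    Reports the Euclidean norm of the vector difference (``d_mag``, the
    primary metric), the absolute difference of magnitudes (``d_mag_abs``),
    and the absolute angle change of the first two coordinates (``d_angle``
    in [0, π]). Cells invalid in either field are excluded.
    """
    if a.cells != b.cells:
        raise ValueError("vector fields describe different cell sets")
    va = _component(a, component)
    vb = _component(b, component)
    if va.shape != vb.shape:
        raise ValueError("vector fields live in different spaces")
    ok = a.valid & b.valid
    va, vb = va[ok], vb[ok]
    d_mag = np.linalg.norm(vb - va, axis=1)
    d_mag_abs = np.abs(np.linalg.norm(vb, axis=1) - np.linalg.norm(va, axis=1))
    d_angle = _angles_between(va, vb)
    return pd.DataFrame(
        {
            "cell": [c for c, k in zip(a.cells, ok) if k],
            "d_mag": d_mag,
            "d_mag_abs": d_mag_abs,
            "d_angle": d_angle,
        }
    )


def shuffled_null(
    tv: TransitionVectors, component: str = "net", seed: int | None = None
) -> np.ndarray:
    """Null distribution of angle changes from random cell pairings.

    Each valid cell's vector is compared against the vector of a uniformly
    drawn *different* valid cell; the angle changes form the baseline
    against which perturbation-induced changes are judged.
    """
    rng = np.random.default_rng(seed)
    vecs = _component(tv, component)[tv.valid]
    n = vecs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 valid cells for a shuffled null")
    partner = rng.integers(0, n - 1, size=n)
    partner[partner >= np.arange(n)] += 1  # uniform over the n−1 others
    return _angles_between(vecs, vecs[partner])


@dataclass
class SensitivityRecord:
    """Effect of one topology perturbation on the inferred field."""

    label: str
    median_d_net: float
    median_d_rev: float
    degenerate: bool
    top15: bool = False
    per_cell: pd.DataFrame | None = None


def edge_sensitivity(
    topology: GRNTopology,
    expression: ExpressionMatrix,
    space: EmbeddingSpace,
    perturbations: list[tuple[str, dict]],
    baseline: TransitionVectors,
    radius_fraction: float | None = None,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    keep_per_cell: bool = False,
) -> list[SensitivityRecord]:
    """Quantify how much each topology perturbation changes the field.

    Each perturbation is a ``(label, kwargs)`` pair where kwargs are
    forwarded to :func:`sticcc.grn.perturb_topology`. Inference is re-run
    on the perturbed topology with the identical embedding and radius, and
    the median per-cell change (Euclidean norm of the vector difference)
    is recorded for net flow and reversibility. Perturbations leaving
    fewer than two edges are recorded degenerate, not computed. Records
    are sorted by combined change, and the top 15% are flagged.
    """
    if radius_fraction is None:
        radius_fraction = baseline.radius_fraction
    records: list[SensitivityRecord] = []
    for label, kwargs in perturbations:
        pert = perturb_topology(topology, **kwargs)
        if pert.degenerate:
            logger.warning("perturbation %r leaves <2 edges; recorded degenerate", label)
            records.append(
                SensitivityRecord(label, float("nan"), float("nan"), degenerate=True)
            )
            continue
        tv = run_sticc(
            pert, expression, space,
            radius_fraction=radius_fraction, min_neighbors=min_neighbors,
        )
        d_net = compare_fields(baseline, tv, "net")
        d_rev = compare_fields(baseline, tv, "rev")
        per_cell = None
        if keep_per_cell:
            per_cell = d_net.rename(columns={"d_mag": "d_net"})[["cell", "d_net"]].merge(
                d_rev.rename(columns={"d_mag": "d_rev"})[["cell", "d_rev"]], on="cell"
            )
        records.append(
            SensitivityRecord(
                label,
                float(d_net["d_mag"].median()),
                float(d_rev["d_mag"].median()),
                degenerate=False,
                per_cell=per_cell,
            )
        )
    scored = [r for r in records if not r.degenerate]
    scored.sort(key=lambda r: r.median_d_net + r.median_d_rev, reverse=True)
    n_top = max(int(np.ceil(0.15 * len(scored))), 1) if scored else 0
    for r in scored[:n_top]:
        r.top15 = True
    ordered = scored + [r for r in records if r.degenerate]
    return ordered


def sensitivity_table(records: list[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "perturbation": [r.label for r in records],
            "d_net": [r.median_d_net for r in records],
            "d_rev": [r.median_d_rev for r in records],
            "degenerate": [r.degenerate for r in records],
            "top15": [r.top15 for r in records],
        }
    )
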