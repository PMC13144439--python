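"""Cross-cell correlation (CCC) and state-transition vector inference.

The method infers, for every cell, where it is headed and where it came
from, using only an expression matrix and a signed regulator→target
network. The premise is a regulatory time delay: changes in a regulator
precede changes in its targets, so if the sign-adjusted regulator profile
of cell i correlates with the target profile of a nearby cell j, then j
looks like a plausible future of i. That propensity is the cross-cell
correlation

    ρ(i→j) = Pearson( e_R(i) ⊙ s , e_T(j) )

taken over network edges, where e_R(i)[k] is the expression of edge k's
regulator in cell i, e_T(j)[k] the expression of its target in cell j, and
s[k] = ±1 the interaction sign (regulator expression is inverted on
inhibitory edges to keep the correlation sign meaningful).

Within a radius-bounded neighborhood of each cell, the local gradient of
ρ(i→·) with respect to relative position x_j − x_i is estimated by least
squares: the outgoing vector v1 points up the gradient of ρ(i→j) (likely
future), and the incoming vector v2 is minus the gradient of ρ(j→i)
(transition away from likely precursors). Their average (v1+v2)/2 is the
net flow — the irreversible component — and half their difference
(v1−v2)/2 is the reversibility, a sign-free bidirectional component.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .grn import GRNTopology
from .matrix import ExpressionMatrix

__all__ = [
    "CCCContext",
    "EmbeddingSpace",
    "Neighborhood",
    "RegressionFit",
    "TransitionVectors",
    "RadiusDiagnostics",
    "compute_ccc",
    "ccc_matrix",
    "find_neighbors",
    "infer_outgoing",
    "infer_incoming",
    "decompose",
    "run_sticc",
    "optimize_radius",
    "DEFAULT_RADIUS_FRACTION",
    "DEFAULT_MIN_NEIGHBORS",
]

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_FRACTION = 0.15
DEFAULT_MIN_NEIGHBORS = 15
#: |y| below this is excluded from percentage-error computations.
MAPE_FLOOR = 1e-9


@dataclass
class CCCContext:
    """Topology + expression bound together for correlation evaluation.

    The expression matrix is restricted to network genes; the regulator and
    target index vectors and the sign vector are aligned with the
    topology's edge order.
    """

    topology: GRNTopology
    expression: ExpressionMatrix
    regulator_idx: np.ndarray
    target_idx: np.ndarray
    signs: np.ndarray

    @classmethod
    def build(cls, topology: GRNTopology, expression: ExpressionMatrix) -> "CCCContext":
        if topology.n_edges < 2:
            raise ValueError(
                "cross-cell correlation needs at least 2 edges "
                f"(got {topology.n_edges})"
            )
        sub = expression.subset_genes(list(topology.genes))
        src, tgt, sgn = topology.edge_arrays()
        return cls(
            topology=topology,
            expression=sub,
            regulator_idx=np.asarray(src, dtype=int),
            target_idx=np.asarray(tgt, dtype=int),
            signs=np.asarray(sgn, dtype=float),
        )

    def regulator_profiles(self) -> np.ndarray:
        """Sign-adjusted regulator expression, cells × edges."""
        E = self.expression.values()
        return E[:, self.regulator_idx] * self.signs[None, :]

    def target_profiles(self) -> np.ndarray:
        E = self.expression.values()
        return E[:, self.target_idx]


@dataclass
class EmbeddingSpace:
    """Coordinates in which neighborhoods and gradients are taken.

    Either the normalized expression of the network genes, principal
    components, or any user-supplied embedding. ``max_pairwise_distance``
    is the scale against which the sampling radius fraction is defined.
    """

    coordinates: np.ndarray
    cells: list[str]
    tag: str = "genes"
    max_pairwise_distance: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] < 2:
            raise ValueError("coordinates must be cells × m with m >= 2")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.max_pairwise_distance <= 0:
            d = pdist(self.coordinates)
            self.max_pairwise_distance = float(d.max()) if d.size else 0.0
        if self.max_pairwise_distance <= 0:
            raise ValueError("all points coincide; embedding is degenerate")

    @classmethod
    def from_expression(cls, expression: ExpressionMatrix, genes: list[str] | None = None):
        sub = expression.subset_genes(genes) if genes else expression
        return cls(sub.values(), cells=sub.cells, tag="genes")

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class Neighborhood:
    """Cells within the sampling radius of a center cell (center excluded)."""

    center: int
    neighbors: np.ndarray
    radius_fraction: float


def compute_ccc(ctx: CCCContext, i: int, j: int) -> float:
    """ρ(i→j): Pearson correlation of sign-adjusted regulators in cell i
    with targets in cell j, over edges. NaN when either profile has zero
    variance across edges (correlation undefined)."""
    r = ctx.regulator_profiles()[i]
    t = ctx.target_profiles()[j]
    rc = r - r.mean()
    tc = t - t.mean()
    denom = np.linalg.norm(rc) * np.linalg.norm(tc)
    if denom == 0.0:
        return float("nan")
    return float(np.clip(rc @ tc / denom, -1.0, 1.0))


def ccc_matrix(ctx: CCCContext) -> np.ndarray:
    """All-pairs CCC: entry [i, j] = ρ(i→j).

    Rows with a zero-variance regulator profile, and columns with a
    zero-variance target profile, are NaN.
    """
    R = ctx.regulator_profiles()
    T = ctx.target_profiles()
    Rc = R - R.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    rn = np.linalg.norm(Rc, axis=1)
    tn = np.linalg.norm(Tc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Rc / np.where(rn == 0, np.nan, rn)[:, None]) @ (
            Tc / np.where(tn == 0, np.nan, tn)[:, None]
        ).T
    return np.clip(C, -1.0, 1.0)


def find_neighbors(space: EmbeddingSpace, i: int, radius_fraction: float) -> Neighborhood:
    """All cells within radius_fraction × max pairwise distance of cell i."""
    if not (0 < radius_fraction <= 1):
        raise ValueError("radius_fraction must lie in (0, 1]")
    radius = radius_fraction * space.max_pairwise_distance
    d = np.linalg.norm(space.coordinates - space.coordinates[i], axis=1)
    nb = np.flatnonzero(d <= radius)
    nb = nb[nb != i]
    return Neighborhood(center=i, neighbors=nb, radius_fraction=radius_fraction)


@dataclass
class RegressionFit:
    """A least-squares gradient fit for one cell.

    ``X`` holds relative positions x_j − x_i (rows per usable neighbor),
    ``y`` the relative CCCs, ``v`` the coefficient vector (the transition
    vector), and ``mape`` the median absolute percentage error of fitted
    versus observed y over entries with |y| above the numerical floor.
    """

    X: np.ndarray
    y: np.ndarray
    v: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    mape: float
    rank_deficient: bool


def _fit(X: np.ndarray, y: np.ndarray) -> RegressionFit:
    v, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ v
    resid = y - fitted
    big = np.abs(y) > MAPE_FLOOR
    mape = float(np.median(np.abs(resid[big] / y[big]))) if big.any() else float("nan")
    return RegressionFit(
        X=X,
        y=y,
        v=v,
        fitted=fitted,
        residuals=resid,
        mape=mape,
        rank_deficient=rank < X.shape[1],
    )


def _neighbor_design(ctx, space, i, neighborhood, ccc, direction):
    """Build (X, y, usable-neighbor mask) for one cell; None if invalid."""
    if np.isnan(ccc[i, i]):
        return None, None, "degenerate_center"
    nb = np.asarray(neighborhood.neighbors, dtype=int)
    if direction == "out":
        y = ccc[i, nb] - ccc[i, i]
    else:
        y = ccc[nb, i] - ccc[i, i]
    ok = ~np.isnan(y)
    return (
        space.coordinates[nb[ok]] - space.coordinates[i],
        y[ok],
        None,
    )


def infer_outgoing(
    ctx: CCCContext,
    space: EmbeddingSpace,
    i: int,
    neighborhood: Neighborhood,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    ccc: np.ndarray | None = None,
) -> RegressionFit:
    """Outgoing transition vector v1 of cell i.

    Regresses y1_j = ρ(i→j) − ρ(i→i) on relative position; v1 is the
    least-squares (minimum-norm when rank-deficient) coefficient vector.
    Neighbors with undefined CCC are dropped; fewer than ``min_neighbors``
    usable neighbors, or an undefined self-correlation, is an error.
    """
    C = ccc if ccc is not None else ccc_matrix(ctx)
    X, y, reason = _neighbor_design(ctx, space, i, neighborhood, C, "out")
    if reason:
        raise ValueError(f"cell {i}: {reason}")
    if len(y) < min_neighbors:
        raise ValueError(
            f"cell {i}: insufficient neighborhood ({len(y)} < {min_neighbors})"
        )
    return _fit(X, y)


def infer_incoming(
    ctx: CCCContext,
    space: EmbeddingSpace,
    i: int,
    neighborhood: Neighborhood,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    ccc: np.ndarray | None = None,
) -> RegressionFit:
    """Incoming transition vector v2 of cell i.

    Regresses y2_j = ρ(j→i) − ρ(i→i) on relative position and negates the
    estimator, so v2 points away from likely precursor states — the same
    orientation convention as v1.
    """
    C = ccc if ccc is not None else ccc_matrix(ctx)
    X, y, reason = _neighbor_design(ctx, space, i, neighborhood, C, "in")
    if reason:
        raise ValueError(f"cell {i}: {reason}")
    if len(y) < min_neighbors:
        raise ValueError(
            f"cell {i}: insufficient neighborhood ({len(y)} < {min_neighbors})"
        )
    fit = _fit(X, y)
    fit.v = -fit.v
    return fit


def decompose(v1: np.ndarray, v2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Net flow (v1+v2)/2 and reversibility (v1−v2)/2."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("v1 and v2 must have the same shape")
    return (v1 + v2) / 2.0, (v1 - v2) / 2.0


@dataclass
class TransitionVectors:
    """Per-cell outgoing/incoming vectors and their decomposition.

    Arrays are cells × m in the embedding space; invalid cells carry NaN
    vectors and a reason code ("insufficient_neighborhood" or
    "degenerate_center").
    """

    cells: list[str]
    space_tag: str
    v1: np.ndarray
    v2: np.ndarray
    net_flow: np.ndarray
    reversibility: np.ndarray
    n_neighbors: np.ndarray
    valid: np.ndarray
    reason: list[str]
    radius_fraction: float = DEFAULT_RADIUS_FRACTION

    def to_frame(self) -> pd.DataFrame:
        m = self.v1.shape[1]
        cols: dict[str, np.ndarray | list] = {"cell": self.cells}
        for name, arr in (
            ("v1", self.v1),
            ("v2", self.v2),
            ("net", self.net_flow),
            ("rev", self.reversibility),
        ):
            for d in range(m):
                cols[f"{name}_{d + 1}"] = arr[:, d]
        cols["n_neighbors"] = self.n_neighbors
        cols["valid"] = self.valid
        cols["reason"] = self.reason
        df = pd.DataFrame(cols)
        df.attrs["space"] = self.space_tag
        return df

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# space: {self.space_tag}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def run_sticc(
    topology: GRNTopology,
    expression: ExpressionMatrix,
    space: EmbeddingSpace | None = None,
    radius_fraction: float = DEFAULT_RADIUS_FRACTION,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
) -> TransitionVectors:
    """Infer per-cell transition vectors for a whole dataset.

    CCCs are always computed on the network-gene expression; the
    regression runs in ``space`` (network-gene coordinates by default).
    Cells whose neighborhood holds fewer than ``min_neighbors`` usable
    neighbors are flagged invalid rather than fitted unstably.
    """
    t0 = time.perf_counter()
    ctx = CCCContext.build(topology, expression)
    if space is None:
        space = EmbeddingSpace.from_expression(ctx.expression)
    if space.n_cells != expression.n_cells:
        raise ValueError(
            "embedding and expression describe different numbers of cells "
            f"({space.n_cells} vs {expression.n_cells})"
        )
    n, m = space.n_cells, space.n_dims
    C = ccc_matrix(ctx)
    radius = radius_fraction * space.max_pairwise_distance
    tree = cKDTree(space.coordinates)
    neighbor_lists = tree.query_ball_point(space.coordinates, r=radius)

    v1 = np.full((n, m), np.nan)
    v2 = np.full((n, m), np.nan)
    n_nb = np.zeros(n, dtype=int)
    valid = np.zeros(n, dtype=bool)
    reasons = ["ok"] * n
    for i in range(n):
        nb = np.asarray([j for j in neighbor_lists[i] if j != i], dtype=int)
        n_nb[i] = nb.size
        if np.isnan(C[i, i]):
            reasons[i] = "degenerate_center"
            continue
        y_out = C[i, nb] - C[i, i]
        y_in = C[nb, i] - C[i, i]
        ok = ~np.isnan(y_out) & ~np.isnan(y_in)
        if int(ok.sum()) < min_neighbors:
            reasons[i] = "insufficient_neighborhood"
            continue
        X = space.coordinates[nb[ok]] - space.coordinates[i]
        v1[i] = _fit(X, y_out[ok]).v
        v2[i] = -_fit(X, y_in[ok]).v
        valid[i] = True
    if not valid.any():
        raise ValueError(
            "no valid cells: the sampling radius may be too small for the "
            "dataset, or the network is degenerate"
        )
    net, rev = decompose(v1, v2)
    elapsed = time.perf_counter() - t0
    with np.errstate(invalid="ignore"):
        logger.info(
            "transition inference: %d/%d valid cells (%.1f%%), median |net|=%.3g, "
            "median |rev|=%.3g, %.2fs",
            int(valid.sum()),
            n,
            100.0 * valid.mean(),
            float(np.median(np.linalg.norm(net[valid], axis=1))),
            float(np.median(np.linalg.norm(rev[valid], axis=1))),
            elapsed,
        )
    return TransitionVectors(
        cells=space.cells,
        space_tag=space.tag,
        v1=v1,
        v2=v2,
        net_flow=net,
        reversibility=rev,
        n_neighbors=n_nb,
        valid=valid,
        reason=reasons,
        radius_fraction=radius_fraction,
    )


DEFAULT_RADIUS_GRID = tuple(np.round(np.linspace(0.05, 0.30, 11), 4))


@dataclass
class RadiusDiagnostics:
    """Grid-search result of the sampling-radius optimization."""

    selected_radius: float
    table: pd.DataFrame  # columns: radius, coverage, mape, score


def optimize_radius(
    topology: GRNTopology,
    expression: ExpressionMatrix,
    space: EmbeddingSpace | None = None,
    candidate_radii: tuple[float, ...] | None = None,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
) -> RadiusDiagnostics:
    """Grid-search the sampling radius to maximize coverage / MAPE.

    Coverage is the fraction of cells with at least ``min_neighbors``
    usable neighbors inside the radius; MAPE is the median over those cells
    of the per-cell median absolute percentage error of the outgoing
    regression (entries with |y| below the numerical floor excluded). The
    default grid is 11 evenly spaced radii on [0.05, 0.30]; ties break
    toward the smaller radius.
    """
    radii = tuple(candidate_radii) if candidate_radii else DEFAULT_RADIUS_GRID
    ctx = CCCContext.build(topology, expression)
    if space is None:
        space = EmbeddingSpace.from_expression(ctx.expression)
    C = ccc_matrix(ctx)
    tree = cKDTree(space.coordinates)
    n = space.n_cells
    if n < min_neighbors + 1:
        raise ValueError(f"need at least {min_neighbors + 1} cells")
    rows = []
    for rf in radii:
        radius = rf * space.max_pairwise_distance
        lists = tree.query_ball_point(space.coordinates, r=radius)
        mapes = []
        covered = 0
        for i in range(n):
            if np.isnan(C[i, i]):
                continue
            nb = np.asarray([j for j in lists[i] if j != i], dtype=int)
            y = C[i, nb] - C[i, i]
            ok = ~np.isnan(y)
            if int(ok.sum()) < min_neighbors:
                continue
            covered += 1
            fit = _fit(space.coordinates[nb[ok]] - space.coordinates[i], y[ok])
            if np.isfinite(fit.mape):
                mapes.append(fit.mape)
        coverage = covered / n
        mape = float(np.median(mapes)) if mapes else float("nan")
        score = coverage / mape if (mape and np.isfinite(mape) and mape > 0) else float("nan")
        rows.append((rf, coverage, mape, score))
    table = pd.DataFrame(rows, columns=["radius", "coverage", "mape", "score"])
    if (table["coverage"] == 0).all():
        raise ValueError(
            "zero coverage at every candidate radius; try a larger grid"
        )
    finite = table["score"].to_numpy()
    if not np.isfinite(finite).any():
        raise ValueError("radius optimization failed: no finite coverage/MAPE score")
    best = int(np.nanargmax(finite))  # first occurrence wins ties → smaller radius
    logger.info(
        "radius optimization: selected %.4g (coverage %.3f, MAPE %.3g)",
        table.loc[best, "radius"],
        table.loc[best, "coverage"],
        table.loc[best, "mape"],
    )
    return RadiusDiagnostics(selected_radius=float(table.loc[best, "radius"]), table=table)
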