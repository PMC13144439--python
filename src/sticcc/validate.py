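"""Validation of predicted vectors against stochastic trajectories.

Ground truth for a transition-vector field is a long noisy simulation of
the same circuit. Near a query point in the projected space, every
trajectory passage is collected as a start point; the displacement to the
state a fixed lag later is an *observed vector*. The distribution of
observed directions is summarized by the peaks of a circular von Mises
kernel density, and a prediction is scored by the cosine similarity to
its nearest peak (so that heterogeneous outcomes — e.g., a bidirectional
path — are not penalized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "ObservedVectorSet",
    "collect_observed_vectors",
    "select_lag",
    "angle_peaks",
    "cosine_score",
    "reversibility_score",
    "validation_report",
]

DEFAULT_CAPTURE_FRACTION = 0.02
DEFAULT_KAPPA = 8.0
DEFAULT_LAG_MAX = 200
_PEAK_FLOOR = 0.20
_GRID = 360


@dataclass
class ObservedVectorSet:
    """Observed displacement vectors anchored near one query point."""

    query: np.ndarray
    capture_fraction: float
    lag: int
    starts: np.ndarray  # timepoint indices
    vectors: np.ndarray  # (n, 2): coords[t+lag] − coords[t]

    @property
    def angles(self) -> np.ndarray:
        return np.arctan2(self.vectors[:, 1], self.vectors[:, 0])


def collect_observed_vectors(
    traj_coords2d: np.ndarray,
    query: np.ndarray,
    capture_fraction: float = DEFAULT_CAPTURE_FRACTION,
    lag: int = 1,
) -> ObservedVectorSet:
    """Observed vectors from all trajectory passages near a query point.

    Start points are the timepoints within ``capture_fraction`` of the
    maximum pairwise trajectory distance from ``query``; each start pairs
    with the state ``lag`` steps later. Starts whose end index would
    overrun the trajectory are dropped. An empty result is allowed (with
    no nearby passage there is nothing to observe).
    """
    coords = np.asarray(traj_coords2d, dtype=float)
    query = np.asarray(query, dtype=float)
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if capture_fraction <= 0:
        raise ValueError("capture_fraction must be positive")
    max_dist = float(pdist(coords).max())
    capture = capture_fraction * max_dist
    d = np.linalg.norm(coords - query, axis=1)
    starts = np.flatnonzero(d <= capture)
    starts = starts[starts + lag < coords.shape[0]]
    vectors = coords[starts + lag] - coords[starts]
    return ObservedVectorSet(
        query=query,
        capture_fraction=capture_fraction,
        lag=lag,
        starts=starts,
        vectors=vectors,
    )


def select_lag(
    traj_coords2d: np.ndarray,
    starts: np.ndarray,
    target_rmsd: float,
    lag_max: int = DEFAULT_LAG_MAX,
) -> int:
    """Pick the lag whose start→end RMSD is closest to a target.

    The lag must be long enough to rise above step-to-step noise but short
    enough to stay local; the target displacement encodes that trade-off
    per dataset. Scans lags 1..lag_max; ties break toward the smaller lag.
    """
    coords = np.asarray(traj_coords2d, dtype=float)
    starts = np.asarray(starts, dtype=int)
    if starts.size == 0:
        raise ValueError("no start points supplied")
    if target_rmsd <= 0:
        raise ValueError("target_rmsd must be positive")
    best_lag, best_err = 1, np.inf
    T = coords.shape[0]
    for lag in range(1, lag_max + 1):
        ok = starts + lag < T
        if not ok.any():
            break
        disp = coords[starts[ok] + lag] - coords[starts[ok]]
        rmsd = float(np.sqrt(np.mean(np.sum(disp**2, axis=1))))
        err = abs(rmsd - target_rmsd)
        if err < best_err:
            best_lag, best_err = lag, err
    return best_lag


def angle_peaks(
    angles: np.ndarray,
    concentration: float = DEFAULT_KAPPA,
    grid_points: int = _GRID,
    floor_fraction: float = _PEAK_FLOOR,
) -> np.ndarray:
    """Peaks of a circular von Mises kernel density of angles.

    The density at θ is the mean of exp(κ·cos(θ − θ_s)) over samples,
    evaluated on a uniform grid over (−π, π]. Circular local maxima above
    ``floor_fraction`` of the global maximum are returned; wrap-around is
    handled so a cluster straddling ±π yields a single peak.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 5:
        raise ValueError("need at least 5 angles for a density estimate")
    grid = np.linspace(-np.pi, np.pi, grid_points, endpoint=False)
    dens = np.mean(np.exp(concentration * np.cos(grid[:, None] - angles[None, :])), axis=1)
    left = np.roll(dens, 1)
    right = np.roll(dens, -1)
    is_peak = (dens >= left) & (dens >= right) & (dens > floor_fraction * dens.max())
    # Plateau ties: keep only the first grid point of each run.
    is_peak &= ~((dens == left) & np.roll(is_peak, 1))
    return grid[is_peak]


def _vector_angle(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    if np.linalg.norm(v[:2]) == 0:
        raise ValueError("zero vector has no direction")
    return float(np.arctan2(v[1], v[0]))


def cosine_score(predicted: np.ndarray, peaks: np.ndarray) -> float:
    """Cosine similarity of a predicted direction to its nearest peak.

    The maximum over peaks of cos(angle(predicted) − peak); 1 means the
    prediction aligns with some observed mode, −1 that it opposes the only
    one. Invariant to positive rescaling of the vector.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        raise ValueError("need at least one peak angle")
    theta = _vector_angle(predicted)
    return float(np.max(np.cos(theta - peaks)))


def reversibility_score(reversibility: np.ndarray, peaks: np.ndarray) -> tuple[float, float]:
    """Score both ends of a bidirectional reversibility vector.

    Reversibility has no preferred sign, so each end (±v) is scored
    against its nearest peak; the pair is returned (forward end first).
    Symmetric under a sign flip of the input up to swapping the pair.
    """
    v = np.asarray(reversibility, dtype=float)
    return cosine_score(v, peaks), cosine_score(-v, peaks)


def validation_report(
    traj_coords2d: np.ndarray,
    queries: np.ndarray,
    predicted: np.ndarray,
    target_rmsd: float,
    capture_fraction: float = DEFAULT_CAPTURE_FRACTION,
    concentration: float = DEFAULT_KAPPA,
    bidirectional: bool = False,
    lag_max: int = DEFAULT_LAG_MAX,
) -> pd.DataFrame:
    """Score predicted vectors at several query points in one pass.

    For each query point: collect starts, pick the lag matching the RMSD
    target, estimate observed-angle peaks, and score the prediction
    (both ends when ``bidirectional``). Queries with no nearby trajectory
    passage or too few observed angles yield a row of NaNs.
    """
    rows = []
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    for q, p in zip(queries, predicted):
        probe = collect_observed_vectors(traj_coords2d, q, capture_fraction, lag=1)
        row: dict = {
            "qx": q[0], "qy": q[1], "n_starts": probe.starts.size,
            "lag": np.nan, "n_peaks": 0, "score": np.nan, "score_rev": np.nan,
        }
        if probe.starts.size >= 5:
            lag = select_lag(traj_coords2d, probe.starts, target_rmsd, lag_max)
            obs = collect_observed_vectors(traj_coords2d, q, capture_fraction, lag=lag)
            nz = np.linalg.norm(obs.vectors, axis=1) > 0
            if int(nz.sum()) >= 5:
                peaks = angle_peaks(obs.angles[nz], concentration)
                row["lag"] = lag
                row["n_peaks"] = peaks.size
                if np.linalg.norm(p[:2]) > 0:
                    if bidirectional:
                        s_fwd, s_bwd = reversibility_score(p, peaks)
                        row["score"], row["score_rev"] = s_fwd, s_bwd
                    else:
                        row["score"] = cosine_score(p, peaks)
        rows.append(row)
    return pd.DataFrame(rows)
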