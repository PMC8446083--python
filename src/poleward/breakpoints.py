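"""Beta-diversity breakpoint analysis along an environmental gradient.

Community tables are reduced to presence-absence, pairwise Sørensen
dissimilarity is summarized to one beta value per station, bivariate
(bagplot) outliers are removed, and a continuous broken-stick ("piecewise")
regression of beta against temperature or altered latitude is searched for
the breakpoint psi with the lowest mean squared error.  The four gap-fill
scenarios probe sensitivity to a missing stretch of the transect by donating
beta values from neighbouring regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .errors import InputError, ScenarioError

#: Temperature search window used for the 16S/18S analyses (deg C).
DEFAULT_TEMPERATURE_WINDOW: tuple[float, float] = (7.0, 29.02)


def altered_latitude(latitude) -> np.ndarray | float:
    """Recode latitude so the North pole is 0, the Equator 90, the South pole 180.

    Maps a pole-to-pole transect onto a single monotone axis; accepts scalars
    or arrays in [-90, 90] degrees.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(lat < -90) or np.any(lat > 90):
        raise InputError("latitude must lie in [-90, 90] degrees")
    out = 90.0 - lat
    return float(out) if np.isscalar(latitude) else out


def presence_absence(table: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Binary table: 1 where abundance is strictly greater than ``threshold``."""
    if threshold < 0:
        raise InputError(f"presence threshold must be >= 0, got {threshold}")
    out = (table > threshold).astype(int)
    out.attrs.update(table.attrs)
    return out


def sorensen_matrix(pa: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Sørensen dissimilarity (b+c)/(2a+b+c) of a presence-absence table."""
    B = pa.to_numpy(dtype=bool)
    empty = pa.index[~B.any(axis=1)]
    if len(empty):
        raise InputError(f"station(s) with no present features: {list(empty[:5])}")
    # Dice distance on booleans is exactly the Sørensen dissimilarity.
    d = squareform(pdist(B, metric="dice"))
    out = pd.DataFrame(d, index=pa.index, columns=pa.index)
    out.attrs["metric"] = "sorensen"
    return out


def station_beta(dist: pd.DataFrame, reduction: str = "mean") -> pd.Series:
    """One beta-diversity value per station from the pairwise matrix.

    Reductions: ``mean`` (mean dissimilarity to all other stations, default),
    ``nearest`` (dissimilarity to the most similar other station), or
    ``adjacent`` (mean of the dissimilarities to the previous/next station in
    the matrix's row order, which the pipeline keeps sorted by latitude).
    """
    n = len(dist.index)
    if n < 3:
        raise InputError(f"need at least 3 stations, got {n}")
    D = dist.to_numpy(dtype=float)
    if reduction == "mean":
        vals = (D.sum(axis=1)) / (n - 1)
    elif reduction == "nearest":
        M = D + np.diag(np.full(n, np.inf))
        vals = M.min(axis=1)
    elif reduction == "adjacent":
        vals = np.empty(n)
        for i in range(n):
            neigh = [j for j in (i - 1, i + 1) if 0 <= j < n]
            vals[i] = np.mean([D[i, j] for j in neigh])
    else:
        raise InputError(f"unknown reduction {reduction!r}")
    return pd.Series(vals, index=dist.index, name="beta")


# ---------------------------------------------------------------------------
# Bagplot outliers via Tukey halfspace depth
# ---------------------------------------------------------------------------


def halfspace_depth(points: np.ndarray, query: np.ndarray | None = None) -> np.ndarray:
    """Exact bivariate Tukey halfspace depth of each query point.

    depth(p) = min over directions d of #{i : d . (x_i - p) >= 0}.  For
    points in general position the minimum is attained with d perpendicular
    to some x_i - p, so it suffices to scan, per query point, the normals of
    all point-to-point directions (both orientations, with a small angular
    nudge to resolve boundary ties).
    """
    X = np.asarray(points, dtype=float)
    Q = X if query is None else np.asarray(query, dtype=float)
    n = len(X)
    depths = np.empty(len(Q), dtype=int)
    eps = 1e-9
    for qi, p in enumerate(Q):
        diff = X - p  # (n, 2)
        norms = np.hypot(diff[:, 0], diff[:, 1])
        nz = norms > 0
        if not nz.any():
            depths[qi] = n
            continue
        ang = np.arctan2(diff[nz, 1], diff[nz, 0])
        # Candidate direction angles: perpendiculars to every connecting
        # segment, nudged both ways.
        cand = np.concatenate(
            [ang + np.pi / 2 + eps, ang + np.pi / 2 - eps,
             ang - np.pi / 2 + eps, ang - np.pi / 2 - eps]
        )
        d = np.stack([np.cos(cand), np.sin(cand)], axis=1)  # (m, 2)
        side = diff @ d.T >= -1e-12  # (n, m): x_i in closed halfplane of d
        depths[qi] = int(side.sum(axis=0).min())
    return depths


def _scale_polygon(vertices: np.ndarray, center: np.ndarray, factor: float) -> np.ndarray:
    return center + factor * (vertices - center)


def bag_outliers(x, y, fence_factor: float = 3.0) -> np.ndarray:
    """Bagplot outlier mask for a bivariate sample.

    The bag is the convex hull of the 50% deepest points (Tukey halfspace
    depth); the fence is the bag inflated by ``fence_factor`` about the depth
    median.  Points outside the fence are flagged True.  Degenerate inputs
    (fewer than 10 points, or collinear) flag nothing and warn.
    """
    import warnings

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    P = np.column_stack([x, y])
    n = len(P)
    if n < 10:
        warnings.warn("fewer than 10 points; bagplot outlier rule disabled")
        return np.zeros(n, dtype=bool)
    depths = halfspace_depth(P)
    median = P[depths == depths.max()].mean(axis=0)
    order = np.argsort(-depths, kind="stable")
    # Smallest depth threshold whose upper level set holds >= half the points.
    k = int(np.ceil(n / 2))
    d_star = depths[order[k - 1]]
    bag_pts = P[depths >= d_star]
    try:
        hull = ConvexHull(bag_pts)
    except QhullError:
        warnings.warn("degenerate (collinear) sample; bagplot outlier rule disabled")
        return np.zeros(n, dtype=bool)
    fence = _scale_polygon(bag_pts[hull.vertices], median, fence_factor)
    path = MplPath(fence)
    inside = path.contains_points(P, radius=1e-9) | path.contains_points(P, radius=-1e-9)
    return ~inside


# ---------------------------------------------------------------------------
# Broken-stick (piecewise) regression
# ---------------------------------------------------------------------------


@dataclass
class BreakpointResult:
    """Continuous broken-stick fit ``y = b0 + b1 x + b2 max(0, x - psi)``.

    ``p_value`` is the F-test of the broken stick against the straight line
    (2 extra parameters: psi and the slope change b2).  Note the Davies
    caveat recorded in ``notes``: psi is unidentified under the null, so the
    F p-value is approximate.
    """

    psi: float
    intercept: float
    slope: float
    slope_change: float
    mse: float
    p_value: float
    n_used: int
    search_range: tuple[float, float]
    notes: str = (
        "p-value from F-test of broken stick vs straight line; approximate "
        "because the breakpoint is unidentified under the null (Davies problem)"
    )

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.intercept, self.slope, self.slope_change)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.intercept + self.slope * x + self.slope_change * np.maximum(0.0, x - self.psi)


def _broken_stick_ols(x: np.ndarray, y: np.ndarray, psi: float) -> tuple[np.ndarray, float]:
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ beta) ** 2))
    return beta, sse


def candidate_breakpoints(
    x: np.ndarray,
    search_range: tuple[float, float] | None,
    min_segment: int,
) -> np.ndarray:
    """Midpoints of consecutive sorted unique x, leaving >= min_segment points per side."""
    ux = np.unique(x)
    mids = (ux[:-1] + ux[1:]) / 2.0
    if search_range is not None:
        lo, hi = search_range
        mids = mids[(mids >= lo) & (mids <= hi)]
    ok = [(np.sum(x < m) >= min_segment) and (np.sum(x > m) >= min_segment) for m in mids]
    return mids[np.asarray(ok, dtype=bool)] if len(mids) else mids


def fit_breakpoint(
    x,
    y,
    search_range: tuple[float, float] | None = None,
    min_segment: int = 3,
) -> BreakpointResult:
    """MSE-minimizing broken-stick regression of y on x.

    Candidate breakpoints are midpoints of consecutive sorted unique x values
    inside ``search_range`` with at least ``min_segment`` points on each
    side; for each candidate an ordinary least squares fit of
    ``y ~ 1 + x + max(0, x - psi)`` is evaluated and the psi with minimal
    mean squared error is returned, together with an F-test against the
    straight-line fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    n = len(x)
    if n < 2 * min_segment + 1:
        raise InputError(f"need >= {2 * min_segment + 1} points, got {n}")
    if np.ptp(x) == 0:
        raise InputError("x is constant; no breakpoint is identifiable")
    cands = candidate_breakpoints(x, search_range, min_segment)
    if len(cands) == 0:
        raise InputError("no candidate breakpoints inside the search range")
    best_psi, best_beta, best_sse = None, None, np.inf
    for psi in cands:
        beta, sse = _broken_stick_ols(x, y, float(psi))
        if sse < best_sse - 1e-15 or best_psi is None:
            best_psi, best_beta, best_sse = float(psi), beta, sse
    # Straight-line null for the F-test.
    X0 = np.column_stack([np.ones_like(x), x])
    b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    sse0 = float(np.sum((y - X0 @ b0) ** 2))
    df_extra, df_resid = 2, n - 4
    if df_resid <= 0 or best_sse <= 0:
        p_value = float("nan") if df_resid <= 0 else 0.0
    else:
        F = ((sse0 - best_sse) / df_extra) / (best_sse / df_resid)
        p_value = float(stats.f.sf(max(F, 0.0), df_extra, df_resid))
    lo = float(cands.min()) if search_range is None else float(search_range[0])
    hi = float(cands.max()) if search_range is None else float(search_range[1])
    return BreakpointResult(
        psi=best_psi,
        intercept=float(best_beta[0]),
        slope=float(best_beta[1]),
        slope_change=float(best_beta[2]),
        mse=best_sse / n,
        p_value=p_value,
        n_used=n,
        search_range=(lo, hi),
    )


# ---------------------------------------------------------------------------
# Gap-fill scenarios
# ---------------------------------------------------------------------------


def scenario_gap_fill(
    beta: pd.Series,
    env: pd.DataFrame,
    gap_stations,
    strategy: str = "nearest_latitude",
    donor_regions: dict[str, list] | None = None,
) -> pd.Series:
    """Fill missing-station beta values from donor stations, by latitude.

    Emulates the sensitivity analysis for a transect gap (the missing North
    Atlantic stretch): each gap station receives the beta value of its donor
    station, chosen nearest by \\|latitude\\| difference (ties broken toward
    the northern donor).

    Strategies: ``nearest_latitude`` (donors = all non-gap stations),
    ``donor_region_A`` / ``donor_region_B`` (donors restricted to the named
    region, e.g. Arctic / South Atlantic), ``both_donors`` (union of A and B).
    ``donor_regions`` maps "A"/"B" to station-id lists for the region
    strategies.
    """
    gap = list(gap_stations)
    missing_env = [s for s in gap if s not in env.index]
    if missing_env:
        raise InputError(f"gap station(s) missing from environment table: {missing_env[:5]}")
    if strategy == "nearest_latitude":
        donors = [s for s in beta.index if s not in gap]
    elif strategy in ("donor_region_A", "donor_region_B", "both_donors"):
        if not donor_regions:
            raise ScenarioError(f"strategy {strategy!r} requires donor_regions")
        if strategy == "donor_region_A":
            donors = list(donor_regions.get("A", []))
        elif strategy == "donor_region_B":
            donors = list(donor_regions.get("B", []))
        else:
            donors = list(donor_regions.get("A", [])) + list(donor_regions.get("B", []))
        donors = [s for s in donors if s in beta.index and s not in gap]
    else:
        raise ScenarioError(f"unknown gap-fill strategy {strategy!r}")
    if not donors:
        raise ScenarioError(f"empty donor pool for strategy {strategy!r}")

    filled = beta.copy()
    donor_lat = env.loc[donors, "latitude"].astype(float)
    for s in gap:
        lat = float(env.loc[s, "latitude"])
        dist = (donor_lat - lat).abs()
        best = dist.min()
        tied = donor_lat[dist <= best + 1e-12]
        donor = tied.idxmax()  # northernmost donor wins ties
        filled.loc[s] = beta.loc[donor]
    return filled
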