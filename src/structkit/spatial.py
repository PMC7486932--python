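"""Spatial structure of ancestry shares: gradient axes, Moran's I, Mantel test.

Coordinates are planar longitude/latitude degrees; by default no
cos-latitude correction is applied (set ``cos_lat=True`` to shrink
longitudes by cos of the mean latitude).  Bearings are compass degrees
clockwise from north: the projection of (lon, lat) on bearing theta is
``lon*sin(theta) + lat*cos(theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class GradientResult:
    """Best-fit spatial axis for an ancestry share.

    ``bearing_deg`` is the compass direction of *increasing* share;
    ``r_squared`` and ``p_value`` come from the simple linear regression of
    the share on the projection along that bearing.
    """

    bearing_deg: float
    r_squared: float
    slope: float
    p_value: float

    def quadrant_label(self) -> str:
        """Render the bearing in quadrant notation (e.g. ``S66°W``) for display."""
        b = self.bearing_deg % 360.0
        if b in (0.0, 360.0):
            return "N"
        if b == 90.0:
            return "E"
        if b == 180.0:
            return "S"
        if b == 270.0:
            return "W"
        if b < 90:
            return f"N{b:.0f}°E"
        if b < 180:
            return f"S{180 - b:.0f}°E"
        if b < 270:
            return f"S{b - 180:.0f}°W"
        return f"N{360 - b:.0f}°W"


def _coords_array(coords, cos_lat: bool) -> np.ndarray:
    xy = np.asarray(coords, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("coords must be (n, 2) of (longitude, latitude)")
    if cos_lat:
        xy = xy.copy()
        xy[:, 0] *= np.cos(np.deg2rad(xy[:, 1].mean()))
    return xy


def gradient_axis_scan(values, coords, step_deg: float = 1.0,
                       cos_lat: bool = False) -> GradientResult:
    """Scan bearings 0..360 for the axis maximising regression r².

    For each bearing theta the values are regressed on the projection
    ``lon*sin(theta) + lat*cos(theta)``; theta and theta+180 give equal r²
    with opposite slope, so the reported bearing is the one with positive
    slope (direction of increasing share).  Ties resolve to the smallest
    bearing.
    """
    v = np.asarray(values, dtype=float)
    xy = _coords_array(coords, cos_lat)
    if len(v) != len(xy):
        raise ValueError("values and coords must have equal length")
    if len(v) < 3:
        raise ValueError("need at least 3 individuals")
    if np.allclose(v, v[0]):
        raise ValueError("constant values: gradient axis undefined")
    thetas = np.arange(0.0, 360.0, step_deg)
    rad = np.deg2rad(thetas)
    proj = xy[:, 0:1] * np.sin(rad)[None, :] + xy[:, 1:2] * np.cos(rad)[None, :]
    pc = proj - proj.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((pc ** 2).sum(axis=0)) * np.sqrt((vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, pc.T @ vc / denom, 0.0)
    # positive slope <=> positive correlation with the projection
    r = np.where(np.isfinite(r), r, 0.0)
    best = int(np.argmax(r))
    if r[best] <= 0:
        raise ValueError("no bearing with positive slope; values may be constant "
                         "along every axis")
    reg = stats.linregress(proj[:, best], v)
    return GradientResult(bearing_deg=float(thetas[best]),
                          r_squared=float(reg.rvalue ** 2),
                          slope=float(reg.slope),
                          p_value=float(reg.pvalue))


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------

def spatial_weights(coords, spec: str = "inverse_distance", k: int = 5,
                    bandwidth: float | None = None,
                    cos_lat: bool = False) -> np.ndarray:
    """Build a spatial weight matrix (zero diagonal).

    ``inverse_distance`` (default): w_ij = 1/d_ij; coincident points are an
    error (use ``knn``).  ``knn``: symmetrized k-nearest-neighbour
    indicator.  ``gaussian``: exp(-d²/2b²) with bandwidth b defaulting to
    the median pairwise distance.
    """
    xy = _coords_array(coords, cos_lat)
    d = squareform(pdist(xy))
    n = len(xy)
    if spec == "inverse_distance":
        off = d[~np.eye(n, dtype=bool)]
        if (off == 0).any():
            raise ValueError("coincident coordinates give infinite inverse-distance "
                             "weights; use the k-nearest-neighbour weight option")
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif spec == "knn":
        if not 1 <= k < n:
            raise ValueError("need 1 <= k < n for knn weights")
        w = np.zeros((n, n))
        order = np.argsort(d + np.diag(np.full(n, np.inf)), axis=1)
        for i in range(n):
            w[i, order[i, :k]] = 1.0
        w = np.maximum(w, w.T)  # symmetrize
    elif spec == "gaussian":
        b = bandwidth if bandwidth is not None else np.median(d[d > 0])
        w = np.exp(-d ** 2 / (2 * b ** 2))
        np.fill_diagonal(w, 0.0)
    else:
        raise ValueError("weight spec must be inverse_distance, knn or gaussian")
    return w


def morans_i(values, coords=None, weight_spec: str = "inverse_distance",
             n_perm: int = 10000, seed: int | None = None,
             weights: np.ndarray | None = None, k: int = 5,
             cos_lat: bool = False) -> tuple[float, float]:
    """Moran's I spatial autocorrelation with a permutation p-value.

    I = (n / sum(w)) * (z' W z / z'z) for centred values z.  The p-value is
    two-sided against the distribution of I under random permutation of
    values over locations, reported as a plain ratio (1/n_perm when no
    permutation is as extreme).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 4:
        raise ValueError("need at least 4 individuals")
    if np.allclose(v, v[0]):
        raise ValueError("constant values: Moran's I undefined")
    if weights is None:
        if coords is None:
            raise ValueError("supply coords or a precomputed weight matrix")
        W = spatial_weights(coords, weight_spec, k=k, cos_lat=cos_lat)
    else:
        W = np.asarray(weights, dtype=float)
    s0 = W.sum()
    z = v - v.mean()

    def stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ W @ zv) / (zv @ zv))

    i_obs = stat(z)
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = stat(rng.permutation(z))
    center = perms.mean()
    count = int(np.sum(np.abs(perms - center) >= abs(i_obs - center) - 1e-12))
    p = count / n_perm if count > 0 else 1.0 / n_perm
    return i_obs, p


def mantel_test(value_dist, geo_dist, n_perm: int = 10000,
                seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; p is the one-sided
    proportion of joint row/column permutations of one matrix with r at
    least the observed (plain ratio, 1/n_perm when none reach it).
    """
    A = np.asarray(value_dist, dtype=float)
    B = np.asarray(geo_dist, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    for name, M in (("value_dist", A), ("geo_dist", B)):
        if not np.allclose(M, M.T):
            raise ValueError(f"{name} must be symmetric")
        if not np.allclose(np.diag(M), 0):
            raise ValueError(f"{name} must have a zero diagonal")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a, b = A[iu], B[iu]
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("constant upper triangle: Mantel r undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        bp = B[np.ix_(p, p)][iu]
        if np.corrcoef(a, bp)[0, 1] >= r_obs - 1e-12:
            count += 1
    pval = count / n_perm if count > 0 else 1.0 / n_perm
    return r_obs, pval
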