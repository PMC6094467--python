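"""Marker ordering by weighted metric MDS and principal-curve projection.

Pairwise recombination fractions are converted to map distances with a map
function, embedded in 2 or 3 dimensions by minimising the LOD- (or LOD^2-)
weighted least-squares stress with SMACOF iterations, and projected onto a
principal curve; arc length along the curve gives the marker order and cM
positions.  Candidate orderings from the different weightings/dimensions
are compared by their mean nearest-informative-neighbour fit (NNfit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from statsmodels.nonparametric.smoothers_lowess import lowess

from .mapfun import get_map_function

WEIGHTINGS = ("lod", "lod2")


def rf_to_distance(r, map_function: str = "haldane"):
    """Map distance in cM from recombination fraction (r >= 0.5 capped)."""
    fwd, _ = get_map_function(map_function)
    return fwd(r)


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def smacof_weighted(D, W, dims=2, init=None, max_iter=300, tol=1e-8):
    """Weighted least-squares metric MDS by SMACOF majorisation.

    Minimises sum_ij W_ij (dhat_ij - D_ij)^2 over configurations X.
    Returns (X, stress).
    """
    n = D.shape[0]
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    D = np.nan_to_num(np.asarray(D, dtype=float), nan=0.0)
    V = np.diag(W.sum(axis=1)) - W
    Vp = np.linalg.pinv(V)
    X = _classical_mds(D, dims) if init is None else np.asarray(init, dtype=float)
    prev = np.inf
    stress = np.inf
    for _ in range(max_iter):
        dist = squareform(pdist(X))
        stress = float((W * (dist - D) ** 2).sum() / 2.0)
        if prev - stress < tol * max(prev, 1.0):
            break
        prev = stress
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, D / dist, 0.0)
        Bm = -W * ratio
        np.fill_diagonal(Bm, 0.0)
        np.fill_diagonal(Bm, -Bm.sum(axis=1))
        X = Vp @ (Bm @ X)
    return X, stress


def _project_to_polyline(points, curve):
    """Arc-length parameter of each point's nearest location on a polyline."""
    seg = np.diff(curve, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_t = np.zeros(len(points))
    best_d = np.full(len(points), np.inf)
    for k in range(len(seg)):
        v = seg[k]
        L2 = seg_len[k] ** 2
        if L2 == 0:
            t = np.zeros(len(points))
        else:
            t = np.clip((points - curve[k]) @ v / L2, 0.0, 1.0)
        proj = curve[k] + t[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_t[upd] = cum[k] + t[upd] * seg_len[k]
    return best_t


def principal_curve(X: np.ndarray, n_iter: int = 10, frac: float = 0.25):
    """Fit a smooth one-dimensional curve through a point cloud.

    Starts from the first principal component and alternates lowess
    smoothing of each coordinate against the current arc-length parameter
    with re-projection of the points onto the smoothed polyline.  Returns
    the arc-length parameter per point.
    """
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    t = Xc @ Vt[0]
    n = len(X)
    frac = min(max(frac, 10.0 / max(n, 10)), 1.0)
    for _ in range(n_iter):
        order = np.argsort(t, kind="stable")
        ts = t[order]
        smooth = np.column_stack([
            lowess(X[order, d], ts, frac=frac, return_sorted=False)
            for d in range(X.shape[1])
        ])
        t_proj = _project_to_polyline(X, smooth)
        if np.allclose(t_proj, t - t.min(), atol=1e-10):
            t = t_proj
            break
        t = t_proj
    return t


@dataclass
class MdsConfiguration:
    coords: np.ndarray
    stress: float
    weighting: str
    dims: int
    outliers: list


@dataclass
class LinkageGroupMap:
    """Ordered markers with cM positions (origin 0, non-decreasing)."""

    markers: list
    positions: np.ndarray
    nnfit: float | None = None
    config: MdsConfiguration | None = None
    dropped: list | None = None

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    @property
    def names(self) -> list:
        return [m.name for m in self.markers]


def largest_connected(lod_matrix: np.ndarray, min_lod: float = 0.0) -> np.ndarray:
    """Indices of the largest connected component of the linkage graph."""
    import networkx as nx

    W = np.array(lod_matrix, dtype=float)
    np.fill_diagonal(W, 0.0)
    g = nx.from_numpy_array((W > min_lod).astype(int))
    comp = max(nx.connected_components(g), key=len)
    return np.array(sorted(comp))


def _check_connected(W):
    import networkx as nx

    g = nx.from_numpy_array((W > 0).astype(int))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise ValueError(
            "weight graph is disconnected; components: "
            + "; ".join(str(sorted(c)) for c in comps)
        )


def mds_order(
    r_matrix: np.ndarray,
    lod_matrix: np.ndarray,
    markers: list | None = None,
    weighting: str = "lod2",
    dims: int = 3,
    map_function: str = "haldane",
    outlier_sd: float = 3.0,
    anchor_positions: np.ndarray | None = None,
):
    """Order one linkage group.

    Returns a :class:`LinkageGroupMap` whose positions come from
    arc-length projection onto a principal curve through the weighted MDS
    configuration, rescaled for consistency with the two-point distances
    and oriented to the anchor positions (where given).
    """
    n = r_matrix.shape[0]
    if n < 4:
        raise ValueError("need at least 4 markers to order")
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    D = rf_to_distance(np.nan_to_num(r_matrix, nan=0.4999), map_function)
    np.fill_diagonal(D, 0.0)
    W = np.array(lod_matrix, dtype=float)
    np.fill_diagonal(W, 0.0)
    W[~np.isfinite(W)] = 0.0
    W[W < 0] = 0.0
    if weighting == "lod2":
        W = W ** 2
    _check_connected(W)

    keep = np.arange(n)
    outliers: list[int] = []
    X, stress = smacof_weighted(D, W, dims=dims)
    # single outlier-removal pass on the mean weighted absolute residual
    dist = squareform(pdist(X))
    wsum = W.sum(axis=1)
    res = (W * np.abs(dist - D)).sum(axis=1) / np.where(wsum > 0, wsum, 1.0)
    med = np.median(res)
    mad = np.median(np.abs(res - med))
    sd = 1.4826 * mad
    if sd > 0:
        # require a large robust z-score AND a residual well above the bulk
        # (with an absolute floor in cM), so locally noisy but consistent
        # markers — or float jitter on exact data — are not discarded
        out_mask = (res > med + outlier_sd * sd) & (res > max(2.0 * med, 0.5))
        if out_mask.any() and out_mask.sum() < n - 3:
            keep = np.flatnonzero(~out_mask)
            # removing outliers can disconnect the graph; keep the largest
            # remaining component rather than failing
            sub = largest_connected(lod_matrix[np.ix_(keep, keep)])
            keep = keep[sub]
            outliers = sorted(set(range(n)) - set(keep.tolist()))
            D = D[np.ix_(keep, keep)]
            W = W[np.ix_(keep, keep)]
            X, stress = smacof_weighted(D, W, dims=dims)

    t = principal_curve(X)
    order_local = np.argsort(t, kind="stable")
    # rescale arc length so weighted pairwise separations match two-point
    # distances; distant pairs are excluded because the map function's
    # inversion saturates there and would shrink the whole group
    dt = np.abs(t[:, None] - t[None, :])
    close = D < 50.0
    num = (W * dt * D)[close].sum()
    den = (W * dt * dt)[close].sum()
    scale = num / den if den > 0 else 1.0
    pos = t[order_local] * scale
    pos = pos - pos[0]
    order = keep[order_local]

    if anchor_positions is not None:
        ref = np.asarray(anchor_positions, dtype=float)[order]
        ok = np.isfinite(ref)
        if ok.sum() >= 2:
            from scipy.stats import spearmanr

            rho = spearmanr(pos[ok], ref[ok]).statistic
            if rho < 0:
                order = order[::-1]
                pos = (pos[-1] - pos)[::-1]

    cfg = MdsConfiguration(coords=X, stress=stress, weighting=weighting,
                           dims=dims, outliers=outliers)
    mk = [markers[i] for i in order] if markers is not None else list(order)
    return LinkageGroupMap(markers=mk, positions=pos, config=cfg,
                           dropped=outliers), order


def nnfit(order: np.ndarray, positions: np.ndarray, r_matrix: np.ndarray,
          lod_matrix: np.ndarray, map_function: str = "haldane") -> float:
    """Mean nearest-informative-neighbour fit of an ordering.

    For each marker, |two-point distance - map distance| to the nearest
    neighbour with non-zero LOD on each side, summed over the available
    sides and averaged over markers.
    """
    order = np.asarray(order)
    n = len(order)
    D = rf_to_distance(np.nan_to_num(r_matrix, nan=0.4999), map_function)
    total = 0.0
    for k in range(n):
        term = 0.0
        for step in (-1, 1):
            j = k + step
            while 0 <= j < n and lod_matrix[order[k], order[j]] <= 0:
                j += step
            if 0 <= j < n:
                obs = D[order[k], order[j]]
                est = abs(positions[k] - positions[j])
                term += abs(obs - est)
        total += term
    return total / n


def select_weighting(
    r_matrix: np.ndarray,
    lod_matrix: np.ndarray,
    markers: list | None = None,
    map_function: str = "haldane",
    anchor_positions: np.ndarray | None = None,
    candidates=(("lod", 2), ("lod", 3), ("lod2", 2), ("lod2", 3)),
):
    """Run MDS under each weighting/dimension and keep the best NNfit order.

    Ties are broken toward LOD^2 weighting in three dimensions.
    """
    results = []
    for weighting, dims in candidates:
        lg, order = mds_order(r_matrix, lod_matrix, markers=markers,
                              weighting=weighting, dims=dims,
                              map_function=map_function,
                              anchor_positions=anchor_positions)
        lg.nnfit = nnfit(order, lg.positions, r_matrix, lod_matrix, map_function)
        results.append(((weighting, dims), lg, order))
    def sort_key(item):
        (weighting, dims), lg, _ = item
        pref = 0 if (weighting, dims) == ("lod2", 3) else 1
        return (round(lg.nnfit, 12), pref)
    results.sort(key=sort_key)
    best = results[0]
    return best[1], best[2], {k: lg.nnfit for k, lg, _ in results}
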