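"""HMM-based QTL interval mapping with permutation thresholds.

At every grid position the trait is regressed on the four inheritance-class
probabilities (means parameterisation, no separate intercept), giving
LOD = (n/2) log10(RSS0/RSS1) against the overall-mean model.  Genome-wide
significance comes from permuting the trait across offspring and taking the
empirical 95th percentile of the genome-wide maximum LOD.  A neighbour-
window comparator computes genotype probabilities from at most k flanking
markers per side, reproducing the irregular profiles that full-information
methods avoid on parentally imbalanced maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hmmengine import InheritanceModel, build_model, posterior_grid
from .markers import MISSING, STATE_LABELS


def genotype_probs(model: InheritanceModel, obs: np.ndarray, step: float = 1.0,
                   grid: np.ndarray | None = None):
    """(grid, o x 4 posterior per position) on a cM grid along the LG."""
    if grid is None:
        lo = float(model.positions[0])
        hi = float(model.positions[-1])
        grid = np.arange(lo, hi + step / 2.0, step)
    post = posterior_grid(model, obs, grid)
    return grid, post


@dataclass
class ScanDesign:
    """Precomputed per-position least-squares pieces for fast (re)scans."""

    grid: np.ndarray
    X: np.ndarray          # (P, n, 4) class probabilities
    pinv: np.ndarray       # (P, 4, n) pseudo-inverses
    xtx_inv: np.ndarray    # (P, 4, 4)
    ok: np.ndarray         # positions with full-rank designs
    lg: np.ndarray | None = None  # LG label per position (genome scans)


def _design(grid, probs, lg_labels=None) -> ScanDesign:
    P, n = probs.shape[1], probs.shape[0]
    X = np.ascontiguousarray(np.swapaxes(probs, 0, 1))  # (P, n, 4)
    pinv = np.empty((X.shape[0], 4, n))
    xtx_inv = np.empty((X.shape[0], 4, 4))
    ok = np.ones(X.shape[0], dtype=bool)
    for p in range(X.shape[0]):
        xtx = X[p].T @ X[p]
        if np.linalg.matrix_rank(xtx) < 4:
            ok[p] = False
            continue
        xtx_inv[p] = np.linalg.inv(xtx)
        pinv[p] = xtx_inv[p] @ X[p].T
    return ScanDesign(grid=np.asarray(grid), X=X, pinv=pinv,
                      xtx_inv=xtx_inv, ok=ok, lg=lg_labels)


def _rss(design: ScanDesign, y: np.ndarray):
    """Per-position residual sums of squares for one or more traits.

    ``y`` is (n,) or (n, T); returns (P, T) RSS1 and (T,) RSS0 plus betas.
    """
    Y = y[:, None] if y.ndim == 1 else y
    beta = np.einsum("pkn,nt->pkt", design.pinv, Y)
    fit = np.einsum("pnk,pkt->pnt", design.X, beta)
    resid = Y[None] - fit
    rss1 = np.einsum("pnt,pnt->pt", resid, resid)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    return rss1, rss0, beta


@dataclass
class QTLScanResult:
    grid: np.ndarray
    lod: np.ndarray
    means: np.ndarray       # (P, 4) class means AC, AD, BC, BD
    ses: np.ndarray         # (P, 4)
    pct_var: np.ndarray
    peak_index: int
    threshold: float | None = None
    support_1lod: tuple | None = None
    support_2lod: tuple | None = None
    nearest_marker: str | None = None
    key_parent: str | None = None

    @property
    def peak_pos(self) -> float:
        return float(self.grid[self.peak_index])

    @property
    def peak_lod(self) -> float:
        return float(self.lod[self.peak_index])


def scan(probs: np.ndarray, trait: np.ndarray, grid: np.ndarray,
         model: InheritanceModel | None = None,
         design: ScanDesign | None = None) -> QTLScanResult:
    """Interval-mapping scan of one trait over one linkage group.

    ``probs`` is (n_offspring, P, 4) genotype probabilities.  Missing trait
    values are dropped listwise.  Positions with rank-deficient designs are
    reported with LOD 0.
    """
    trait = np.asarray(trait, dtype=float)
    keep = np.isfinite(trait)
    if keep.sum() < 30:
        raise ValueError("need at least 30 non-missing offspring")
    y = trait[keep]
    n = y.size
    if design is None:
        design = _design(grid, probs[keep])
    rss1, rss0, beta = _rss(design, y)
    rss1 = rss1[:, 0]
    rss0 = float(rss0[0])
    P = len(design.grid)
    lod = np.zeros(P)
    pct = np.zeros(P)
    means = np.full((P, 4), np.nan)
    ses = np.full((P, 4), np.nan)
    okp = design.ok & (rss1 > 0) & (rss0 > 0)
    lod[okp] = np.maximum((n / 2.0) * np.log10(rss0 / rss1[okp]), 0.0)
    pct[okp] = 100.0 * (1.0 - rss1[okp] / max(rss0, 1e-300))
    means[design.ok] = beta[design.ok, :, 0]
    dof = max(n - 4, 1)
    sigma2 = np.maximum(rss1, 0.0) / dof
    for p in np.flatnonzero(design.ok):
        ses[p] = np.sqrt(np.diag(design.xtx_inv[p]) * sigma2[p])
    peak = int(np.argmax(lod))  # argmax ties break leftmost
    res = QTLScanResult(grid=design.grid, lod=lod, means=means, ses=ses,
                        pct_var=pct, peak_index=peak)
    res.support_1lod = support_interval(design.grid, lod, peak, 1.0)
    res.support_2lod = support_interval(design.grid, lod, peak, 2.0)
    if model is not None:
        k = np.argmin(np.abs(model.positions - res.peak_pos))
        res.nearest_marker = model.markers[k].name
        res.key_parent = key_parent(means[peak], ses[peak], n)
    return res


def support_interval(grid: np.ndarray, lod: np.ndarray, peak: int,
                     drop: float = 1.0) -> tuple:
    """Maximal contiguous interval around the peak with LOD >= peak - drop."""
    thr = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    return float(grid[lo]), float(grid[hi])


def key_parent(means: np.ndarray, ses: np.ndarray, n: int,
               alpha: float = 0.05) -> str:
    """Which parent's allele substitution drives the QTL.

    The Latham contrast compares (AC+AD)/2 with (BC+BD)/2, the Moy contrast
    (AC+BC)/2 with (AD+BD)/2; each is tested with a t-test on n-4 df.
    """
    c_lat = (means[0] + means[1] - means[2] - means[3]) / 2.0
    c_moy = (means[0] + means[2] - means[1] - means[3]) / 2.0
    se = np.sqrt((ses ** 2).sum()) / 2.0
    dof = max(n - 4, 1)
    sig = []
    for c in (c_lat, c_moy):
        t = c / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), dof)
        sig.append(p < alpha)
    if all(sig):
        return "Both"
    if sig[0]:
        return "Latham"
    if sig[1]:
        return "Moy"
    return "none"


def genome_design(models: list, observations: list, step: float = 1.0) -> ScanDesign:
    """Stack per-LG genotype probabilities into one genome-wide design."""
    grids, probs, labels = [], [], []
    for lg, (model, obs) in enumerate(zip(models, observations)):
        g, p = genotype_probs(model, obs, step)
        grids.append(g)
        probs.append(p)
        labels.append(np.full(g.size, lg))
    grid = np.concatenate(grids)
    prob = np.concatenate(probs, axis=1)
    return _design(grid, prob, lg_labels=np.concatenate(labels))


def permutation_threshold(design: ScanDesign, trait: np.ndarray,
                          n_perm: int = 200, alpha: float = 0.05,
                          seed: int = 0, block: int = 50) -> float:
    """Genome-wide LOD threshold from trait permutations.

    Permutes the trait across offspring, records the genome-wide maximum
    LOD per permutation, and returns the empirical (1 - alpha) quantile.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    trait = np.asarray(trait, dtype=float)
    keep = np.isfinite(trait)
    y = trait[keep]
    n = y.size
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    okp = design.ok
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        Y = np.empty((n, b))
        for t in range(b):
            Y[:, t] = rng.permutation(y)
        rss1, rss0, _ = _rss(design, Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = (n / 2.0) * np.log10(rss0[None, :] / rss1)
        lod = np.where(okp[:, None] & (rss1 > 0) & (rss0 > 0)[None, :],
                       np.maximum(lod, 0.0), 0.0)
        maxima[done:done + b] = lod.max(axis=0)
        done += b
    return float(np.quantile(maxima, 1.0 - alpha))


def neighbor_window_probs(model: InheritanceModel, obs: np.ndarray,
                          step: float = 1.0, k: int = 5,
                          grid: np.ndarray | None = None):
    """Genotype probabilities from at most k nearest non-missing markers
    per side of each grid position (the neighbour-window comparator).

    Offspring sharing a missingness pattern inside a window are processed
    together.  Returns (grid, (n_offspring, P, 4) probabilities).
    """
    obs = np.atleast_2d(np.asarray(obs))
    n, m = obs.shape
    if grid is None:
        lo = float(model.positions[0])
        hi = float(model.positions[-1])
        grid = np.arange(lo, hi + step / 2.0, step)
    out = np.empty((n, grid.size, 4))
    pos = model.positions
    nonmiss = obs != MISSING
    complete = bool(nonmiss.all())
    for gi, gpos in enumerate(grid):
        right = int(np.searchsorted(pos, gpos))
        # group offspring by identical windows of non-missing markers
        windows: dict[tuple, list] = {}
        if complete:
            w = tuple(range(max(right - k, 0), min(right + k, m)))
            windows[w] = list(range(n))
        else:
            for i in range(n):
                left_idx = [j for j in range(right - 1, -1, -1) if nonmiss[i, j]][:k]
                right_idx = [j for j in range(right, m) if nonmiss[i, j]][:k]
                w = tuple(sorted(left_idx + right_idx))
                windows.setdefault(w, []).append(i)
        for w, members in windows.items():
            rows = np.array(members)
            if not w:
                out[rows, gi] = 0.25
                continue
            mk = [model.markers[j] for j in w]
            sub = build_model(mk, model.error_rate, model.map_function,
                             positions=pos[list(w)])
            post = posterior_grid(sub, obs[np.ix_(rows, list(w))],
                                  np.array([gpos]))
            out[rows, gi] = post[:, 0, :]
    return grid, out


def profile_roughness(lod: np.ndarray) -> float:
    """Mean absolute second difference of a LOD profile."""
    return float(np.abs(np.diff(lod, 2)).mean())
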