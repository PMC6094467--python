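"""QTL-ready traits from plot-level ripening score profiles.

Fruit development is scored repeatedly on a 1-7 ordinal scale (1 = bud
break, 2 = open flowers, 3 = fruit set, 4 = green fruit, 5 = green/red
fruit, 6 = red fruit, 7 = over-ripe).  Profiles are summarised two ways:
principal coordinates of the city-block distance matrix between plot
profiles, keeping axes that differ significantly among offspring
genotypes; and the interpolated time (days) to reach each of stages 2-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats


@dataclass
class RipeningProfiles:
    """Plot x date score matrix with the plot -> genotype mapping."""

    scores: np.ndarray  # (n_plots, n_dates) ints on the 1-7 scale
    dates: np.ndarray   # strictly increasing days
    genotype: np.ndarray  # offspring-genotype index per plot

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        self.dates = np.asarray(self.dates, dtype=float)
        self.genotype = np.asarray(self.genotype)
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")


def pco_scores(profiles: RipeningProfiles | np.ndarray):
    """Principal coordinates of the city-block distances between plots.

    Classical scaling: double-centre -D^2/2 and eigendecompose.
    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; all eigenvalues (including negatives, which flag a
    non-Euclidean L1 configuration) are returned, sorted descending.
    Each axis is oriented so it correlates non-negatively with the mean
    score over dates ("high PCO1 = slower ripening" stays reproducible).
    """
    X = profiles.scores if isinstance(profiles, RipeningProfiles) else np.asarray(profiles)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 plots")
    D = squareform(pdist(X.astype(float), metric="cityblock"))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    summary = X.mean(axis=1)
    for a in range(coords.shape[1]):
        if coords[:, a].std() > 0 and np.corrcoef(coords[:, a], summary)[0, 1] < 0:
            coords[:, a] = -coords[:, a]
    return coords, vals


def select_axes(coords: np.ndarray, genotype: np.ndarray,
                alpha: float = 0.001):
    """Keep axes with significant among-genotype differences.

    One-way ANOVA per axis over genotypes (needs replicate plots); the
    genotype means of retained axes become the QTL-mapping traits.
    Without replication, selection is skipped and every axis passed
    through.  Returns (retained axis indices, genotype x axis means,
    p-values).
    """
    genotype = np.asarray(genotype)
    groups, inverse = np.unique(genotype, return_inverse=True)
    replicated = np.bincount(inverse).min() >= 2 and groups.size >= 2
    pvals = np.ones(coords.shape[1])
    if replicated:
        for a in range(coords.shape[1]):
            samples = [coords[inverse == g, a] for g in range(groups.size)]
            pvals[a] = stats.f_oneway(*samples).pvalue
        retained = np.flatnonzero(pvals < alpha)
    else:
        retained = np.arange(coords.shape[1])
    means = np.empty((groups.size, coords.shape[1]))
    for g in range(groups.size):
        means[g] = coords[inverse == g].mean(axis=0)
    return retained, means, pvals


def interpolate_stage_times(profiles: RipeningProfiles,
                            stages=range(2, 7)) -> pd.DataFrame:
    """Days to reach each developmental stage, linearly interpolated.

    Score decreases (rare recording slips) are cleaned with a running
    maximum.  A stage already reached at the first scoring date gets that
    date; a stage never reached is missing.
    """
    S = np.maximum.accumulate(profiles.scores, axis=1).astype(float)
    d = profiles.dates
    out = {}
    for s in stages:
        col = np.full(S.shape[0], np.nan)
        for i in range(S.shape[0]):
            row = S[i]
            if row[0] >= s:
                col[i] = d[0]
                continue
            idx = np.flatnonzero(row >= s)
            if idx.size == 0:
                continue
            j = idx[0]
            col[i] = d[j - 1] + (s - row[j - 1]) * (d[j] - d[j - 1]) / (row[j] - row[j - 1])
        out[f"stage{s}"] = col
    return pd.DataFrame(out)


def genotype_trait_table(profiles: RipeningProfiles, alpha: float = 0.001,
                         stage_alpha: float = 0.05) -> pd.DataFrame:
    """Full trait pipeline: PCO axes + stage times, aggregated by genotype.

    PCO axes are screened at ``alpha``; stage-time traits at the looser
    ``stage_alpha``.  Genotype means over replicate plots are returned,
    indexed by genotype, with PCO columns named PCO<k> (1-based by
    eigenvalue rank).
    """
    coords, _ = pco_scores(profiles)
    retained, means, _ = select_axes(coords, profiles.genotype, alpha)
    groups = np.unique(profiles.genotype)
    data = {f"PCO{a + 1}": means[:, a] for a in retained}
    st = interpolate_stage_times(profiles)
    inverse = np.searchsorted(groups, profiles.genotype)
    for col in st.columns:
        v = st[col].to_numpy()
        ok = np.isfinite(v)
        samples = [v[(profiles.genotype == g) & ok] for g in groups]
        samples = [s for s in samples if s.size >= 2]
        if len(samples) < 2:
            continue
        p = stats.f_oneway(*samples).pvalue
        if not np.isfinite(p) or p >= stage_alpha:
            continue
        gmean = np.full(groups.size, np.nan)
        for gi, g in enumerate(groups):
            rows = (profiles.genotype == g) & ok
            if rows.any():
                gmean[gi] = v[rows].mean()
        data[col] = gmean
    return pd.DataFrame(data, index=groups)
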