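"""Two-point linkage: recombination fractions, LODs, phases, pre-filters.

For every marker pair the recombination fraction is estimated by maximum
likelihood over the joint phenotype-class counts, with the inheritance
states of the two parents as latent variables (expectation-maximisation).
The model is sex-averaged: one r per pair, with each parent's homolog
switching independently.  All four relative linkage phases (flip the second
marker's Latham and/or Moy homolog labels) are fitted and the best kept.
Pairs heterozygous in different single parents carry no information about
recombination and are flagged (LOD 0).

Phases are propagated along maximum spanning trees of the LOD-weighted
phase graphs (one per parent) to produce an absolutely phased marker list
for the HMM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MISSING, N_CLASSES, PhasedMarker, expected_class_ratio

R_MIN, R_MAX = 1e-6, 0.4999
LOD_CAP = 50.0

#: state permutations implementing a phase flip of the second marker
_PERM_FLIP_L = np.array([2, 3, 0, 1])
_PERM_FLIP_M = np.array([1, 0, 3, 2])
_PHASES = ((0, 0), (1, 0), (0, 1), (1, 1))

_S = np.arange(4)
_SWITCH_L = ((_S[:, None] >> 1) != (_S[None, :] >> 1)).astype(float)
_SWITCH_M = ((_S[:, None] & 1) != (_S[None, :] & 1)).astype(float)


def _indicator_emissions(markers, error_rate=0.0):
    """(M, 4 states, N_CLASSES) emission tensors; states with unobservable
    phenotype get all-zero rows (their offspring are recorded missing)."""
    E = np.zeros((len(markers), 4, N_CLASSES))
    for k, m in enumerate(markers):
        ph = m.phenotype_codes()
        classes = m.observable_classes()
        c = len(classes)
        for s in range(4):
            if ph[s] == MISSING:
                continue
            if error_rate > 0 and c > 1:
                E[k, s, classes] = error_rate / (c - 1)
                E[k, s, ph[s]] = 1.0 - error_rate
            else:
                E[k, s, ph[s]] = 1.0
    return E


def _joint_counts(calls, pairs):
    """(P, C, C) joint phenotype-class counts, missing dropped pairwise."""
    P = len(pairs)
    A = calls[pairs[:, 0]]
    B = calls[pairs[:, 1]]
    ok = (A != MISSING) & (B != MISSING)
    rows = np.repeat(np.arange(P), calls.shape[1])[ok.ravel()]
    flat = (A * N_CLASSES + B).ravel()[ok.ravel()]
    N = np.zeros((P, N_CLASSES * N_CLASSES))
    np.add.at(N, (rows, flat), 1.0)
    return N.reshape(P, N_CLASSES, N_CLASSES)


def _transition_batch(r):
    t = np.empty((r.size, 2, 2))
    t[:, 0, 0] = t[:, 1, 1] = 1.0 - r
    t[:, 0, 1] = t[:, 1, 0] = r
    return np.einsum("buw,bvx->buvwx", t, t).reshape(r.size, 4, 4)


def _loglik_K(N, K, T):
    J = 0.25 * np.einsum("bstij,bst->bij", K, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        logJ = np.where(J > 0, np.log(np.maximum(J, 1e-300)), -np.inf)
        terms = np.where(N > 0, N * logJ, 0.0)
    return terms.sum(axis=(1, 2)), J


def _em_batch(N, E1, E2, r0=0.25, max_iter=200, tol=1e-6):
    """Batched EM for r over a (pair x phase) batch; returns (r, loglik).

    Converged batch members are frozen, so slowly converging weak pairs do
    not drag the whole batch through the full iteration budget.
    """
    B = N.shape[0]
    r = np.full(B, r0)
    K = np.einsum("bsi,btj->bstij", E1, E2)  # pair kernel, fixed over EM
    n_obs = np.maximum(N.sum(axis=(1, 2)), 1.0)
    active = np.arange(B)
    for _ in range(max_iter):
        if active.size == 0:
            break
        Ta = _transition_batch(r[active])
        _, J = _loglik_K(N[active], K[active], Ta)
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(J > 0, N[active] / np.maximum(J, 1e-300), 0.0)
        C = 0.25 * np.einsum("bij,bstij->bst", W, K[active])
        EL = (C * Ta * _SWITCH_L).sum(axis=(1, 2))
        EM_ = (C * Ta * _SWITCH_M).sum(axis=(1, 2))
        r_new = np.clip((EL + EM_) / (2.0 * n_obs[active]), R_MIN, R_MAX)
        moved = np.abs(r_new - r[active]) >= tol
        r[active] = r_new
        active = active[moved]
    ll, _ = _loglik_K(N, K, _transition_batch(r))
    return r, ll


def informative_parents(marker: PhasedMarker) -> tuple[bool, bool]:
    return marker.informative_for()


def pair_informative(m1: PhasedMarker, m2: PhasedMarker) -> bool:
    """A pair is informative iff the markers share an informative parent."""
    l1, mo1 = m1.informative_for()
    l2, mo2 = m2.informative_for()
    return (l1 and l2) or (mo1 and mo2)


def estimate_pairwise(
    markers: list,
    calls: np.ndarray,
    pairs: np.ndarray | None = None,
    error_rate: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """EM estimates of r, LOD and phase for marker pairs.

    ``calls`` is (n_markers, n_offspring) of phenotype codes.  Returns a
    DataFrame with columns i, j, r, lod, flip_latham, flip_moy,
    informative.  Uninformative pairs get r = NaN, LOD = 0.
    """
    M = len(markers)
    if pairs is None:
        ii, jj = np.triu_indices(M, k=1)
        pairs = np.column_stack([ii, jj])
    pairs = np.asarray(pairs)
    info = np.array([pair_informative(markers[i], markers[j]) for i, j in pairs])
    E = _indicator_emissions(markers, error_rate)
    Np = _joint_counts(calls, pairs)

    idx = np.flatnonzero(info)
    P = len(idx)
    out_r = np.full(len(pairs), np.nan)
    out_lod = np.zeros(len(pairs))
    out_fl = np.zeros(len(pairs), dtype=np.int8)
    out_fm = np.zeros(len(pairs), dtype=np.int8)
    if P:
        # batch = informative pairs x 4 phases
        E1 = np.repeat(E[pairs[idx, 0]], 4, axis=0)
        E2_base = E[pairs[idx, 1]]
        variants = []
        for fl, fm in _PHASES:
            perm = np.arange(4)
            if fl:
                perm = _PERM_FLIP_L[perm]
            if fm:
                perm = _PERM_FLIP_M[perm]
            variants.append(E2_base[:, perm, :])
        E2 = np.stack(variants, axis=1).reshape(P * 4, 4, N_CLASSES)
        Nb = np.repeat(Np[idx], 4, axis=0)
        r_b, ll_b = _em_batch(Nb, E1, E2, max_iter=max_iter, tol=tol)
        # at r = 0.5 the transition is uniform, so the joint factorises
        J05 = np.einsum("bi,bj->bij", E1.sum(axis=1), E2.sum(axis=1)) / 16.0
        with np.errstate(divide="ignore", invalid="ignore"):
            logJ = np.where(J05 > 0, np.log(np.maximum(J05, 1e-300)), -np.inf)
            ll05 = np.where(Nb > 0, Nb * logJ, 0.0).sum(axis=(1, 2))
        r_b = r_b.reshape(P, 4)
        ll_b = ll_b.reshape(P, 4)
        ll05 = ll05.reshape(P, 4)
        best = ll_b.argmax(axis=1)
        rows = np.arange(P)
        need_eps = ~np.isfinite(ll_b[rows, best])
        if need_eps.any() and error_rate == 0.0:
            # structurally impossible cells from miscalls: refit with a leak
            sub = idx[need_eps]
            redo = estimate_pairwise(markers, calls, pairs[sub], error_rate=1e-4,
                                     max_iter=max_iter, tol=tol)
            for row, (_, rec) in zip(sub, redo.iterrows()):
                out_r[row] = rec["r"]
                out_lod[row] = rec["lod"]
                out_fl[row] = rec["flip_latham"]
                out_fm[row] = rec["flip_moy"]
        ok = ~need_eps
        out_r[idx[ok]] = r_b[rows, best][ok]
        with np.errstate(invalid="ignore"):
            lod = (ll_b[rows, best] - ll05[rows, best]) / np.log(10.0)
        out_lod[idx[ok]] = np.maximum(lod[ok], 0.0)
        fl = np.array([_PHASES[b][0] for b in best], dtype=np.int8)
        fm = np.array([_PHASES[b][1] for b in best], dtype=np.int8)
        out_fl[idx[ok]] = fl[ok]
        out_fm[idx[ok]] = fm[ok]
    return pd.DataFrame({
        "i": pairs[:, 0], "j": pairs[:, 1],
        "r": out_r, "lod": out_lod,
        "flip_latham": out_fl, "flip_moy": out_fm,
        "informative": info,
    })


def estimate_rf(m1: PhasedMarker, m2: PhasedMarker, calls1, calls2, **kw):
    """Single-pair convenience wrapper; returns a pandas Series."""
    calls = np.vstack([calls1, calls2])
    df = estimate_pairwise([m1, m2], calls, pairs=np.array([[0, 1]]), **kw)
    return df.iloc[0]


def pairwise_matrices(markers: list, calls: np.ndarray, **kw):
    """Symmetric r and LOD matrices for a marker group (>= 3 markers)."""
    M = len(markers)
    if M < 3:
        raise ValueError("need at least 3 markers")
    df = estimate_pairwise(markers, calls, **kw)
    r = np.zeros((M, M))
    lod = np.full((M, M), 0.0)
    r[:] = np.nan
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, LOD_CAP)
    for i, j, rv, lv in zip(df["i"], df["j"], df["r"], df["lod"]):
        r[i, j] = r[j, i] = rv
        lod[i, j] = lod[j, i] = lv
    return r, lod, df


# ---------------------------------------------------------------------------
# pre-ordering marker filters


def segregation_distortion_p(marker: PhasedMarker, calls_row: np.ndarray) -> float:
    """Chi-square goodness-of-fit p-value against the Mendelian ratio."""
    ratio = expected_class_ratio(marker)
    obs = calls_row[calls_row != MISSING]
    if obs.size == 0:
        return 1.0
    classes = sorted(ratio)
    counts = np.array([(obs == c).sum() for c in classes], dtype=float)
    expected = np.array([ratio[c] for c in classes]) * counts.sum()
    if len(classes) < 2:
        return 1.0
    return float(stats.chisquare(counts, expected).pvalue)


def prefilter(markers: list, calls: np.ndarray, round: int = 1,
              max_missing_round1: int = 40, min_missing_round2: int = 45,
              distortion_alpha: float = 1e-4) -> pd.DataFrame:
    """Pre-ordering exclusions: duplicates, missingness, distortion.

    Round 1 collapses duplicate call vectors, drops markers with more than
    ``max_missing_round1`` missing values and markers with extreme
    segregation distortion (chi-square p below ``distortion_alpha``).
    Round 2 drops only markers with ``min_missing_round2`` or more missing
    values.  Returns a per-marker report with a ``retained`` column.
    """
    M = len(markers)
    n_missing = (calls == MISSING).sum(axis=1)
    reason = np.array([""] * M, dtype=object)
    if round == 1:
        seen: dict[bytes, int] = {}
        for k in range(M):
            key = calls[k].tobytes()
            if key in seen:
                reason[k] = f"duplicate_of:{markers[seen[key]].name}"
            else:
                seen[key] = k
        over = (n_missing > max_missing_round1) & (reason == "")
        reason[over] = "missing"
        for k in range(M):
            if reason[k]:
                continue
            if segregation_distortion_p(markers[k], calls[k]) < distortion_alpha:
                reason[k] = "distorted"
    elif round == 2:
        reason[n_missing >= min_missing_round2] = "missing"
    else:
        raise ValueError("round must be 1 or 2")
    return pd.DataFrame({
        "name": [m.name for m in markers],
        "n_missing": n_missing,
        "reason": reason,
        "retained": reason == "",
    })


# ---------------------------------------------------------------------------
# phase propagation


def phase_markers(markers: list, pair_df: pd.DataFrame, min_lod: float = 1.0,
                  strict: bool = False):
    """Resolve absolute phases by spanning trees over the phase graphs.

    One LOD-weighted graph per parent is built from informative pairs; the
    phase flips along a maximum spanning tree fix every marker's homolog
    labelling relative to the component root.  Markers left in no component
    (or in secondary components) have unresolved phase; with ``strict``
    that raises, otherwise they are reported.

    Pairs of parent-symmetric markers (e.g. two ABxAB markers, whose
    phenotype is invariant to swapping the parental homolog labels) cannot
    distinguish a Latham flip from a Moy flip under the sex-averaged model
    and are excluded from the phase graphs; such markers are phased via
    single-parent or asymmetric neighbours instead.

    Returns (phased marker list, flips (M, 2) int8, unresolved name list).
    """
    import networkx as nx

    M = len(markers)
    flips = np.zeros((M, 2), dtype=np.int8)
    unresolved: set[int] = set()
    info = np.array([m.informative_for() for m in markers], dtype=bool)

    sym = np.array([m.informative_for() == (True, True)
                    and m.phenotype_codes()[1] == m.phenotype_codes()[2]
                    for m in markers], dtype=bool)
    for parent, flip_col in ((0, "flip_latham"), (1, "flip_moy")):
        g = nx.Graph()
        nodes = np.flatnonzero(info[:, parent])
        g.add_nodes_from(nodes.tolist())
        for _, row in pair_df.iterrows():
            i, j = int(row["i"]), int(row["j"])
            if row["lod"] < min_lod or not row["informative"]:
                continue
            if sym[i] and sym[j]:
                continue
            if info[i, parent] and info[j, parent]:
                g.add_edge(i, j, weight=float(row["lod"]), flip=int(row[flip_col]))
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        for ci, comp in enumerate(comps):
            tree = nx.maximum_spanning_tree(g.subgraph(comp), weight="weight")
            root = min(comp)
            parity = {root: 0}
            for u, v in nx.bfs_edges(tree, root):
                parity[v] = parity[u] ^ tree.edges[u, v]["flip"]
            for node, par in parity.items():
                flips[node, parent] = par
            if ci > 0:
                unresolved.update(comp)
    names = sorted(markers[i].name for i in unresolved)
    if strict and names:
        raise ValueError(f"unresolved phases for markers: {names}")
    phased = [m.flipped(bool(flips[k, 0]), bool(flips[k, 1]))
              for k, m in enumerate(markers)]
    return phased, flips, names
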