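"""Hidden Markov model over offspring inheritance states.

At each locus an offspring is in one of four states AC, AD, BC, BD (which
homolog it inherited from each parent).  Between adjacent loci d cM apart
each parent's homolog switches independently with probability r(d) from
the map function, so the 4x4 transition matrix factorises into two 2x2
switch/stay matrices.  Emissions compare the observed phenotype class with
the one implied by the state through the marker's phased parental alleles,
allowing a genotyping-error rate eps.

The model serves three purposes: reconstructing inheritance paths to count
recombinations (map checking), improving marker orders by greedy local
moves, and producing QTL genotype probabilities on a cM grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .mapfun import get_map_function, haldane_d
from .markers import MISSING, PhasedMarker, emission_matrix


@dataclass
class InheritanceModel:
    markers: list
    positions: np.ndarray
    error_rate: float
    map_function: str
    r: np.ndarray  # (m-1,) interval recombination fractions
    emissions: np.ndarray  # (m, 4, n_phenotype_classes)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def transition(self, k: int) -> np.ndarray:
        r = self.r[k]
        t2 = np.array([[1 - r, r], [r, 1 - r]])
        return np.kron(t2, t2)


def build_model(
    markers: list,
    error_rate: float = 0.01,
    map_function: str = "haldane",
    positions: np.ndarray | None = None,
) -> InheritanceModel:
    """Assemble the HMM for an ordered, phased linkage group."""
    if positions is None:
        positions = np.array([m.pos for m in markers], dtype=float)
    else:
        positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) < -1e-9):
        raise ValueError("marker positions must be sorted")
    _, inv = get_map_function(map_function)
    r = inv(np.maximum(np.diff(positions), 0.0))
    B = np.stack([emission_matrix(m, error_rate) for m in markers])
    return InheritanceModel(
        markers=list(markers), positions=positions,
        error_rate=error_rate, map_function=map_function, r=r, emissions=B,
    )


def _obs_likelihood(model: InheritanceModel, obs: np.ndarray, k: int) -> np.ndarray:
    """(n_off, 4) emission likelihood at locus k; missing rows are ones."""
    o = obs[:, k]
    e = np.ones((o.size, 4))
    valid = o != MISSING
    if valid.any():
        e[valid] = model.emissions[k][:, o[valid]].T
        bad = valid & (e.sum(axis=1) <= 0)
        if bad.any():
            raise ValueError(
                f"zero emission probability at locus {k} for observed class; "
                "use a positive error rate"
            )
    return e


def forward_backward(model: InheritanceModel, obs: np.ndarray):
    """Posterior state probabilities and per-offspring log-likelihood.

    ``obs`` is (n_offspring, m) of phenotype-class codes with MISSING = -1.
    Uses the scaled linear-domain recursions, so underflow cannot occur.
    Returns (posteriors (n, m, 4), loglik (n,)).
    """
    obs = np.atleast_2d(np.asarray(obs))
    n, m = obs.shape
    if m != model.n_markers:
        raise ValueError("observation width does not match model")
    alpha = np.empty((n, m, 4))
    scale = np.empty((n, m))
    a = 0.25 * _obs_likelihood(model, obs, 0)
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0:1]
    for k in range(1, m):
        a = (alpha[:, k - 1] @ model.transition(k - 1)) * _obs_likelihood(model, obs, k)
        scale[:, k] = a.sum(axis=1)
        alpha[:, k] = a / scale[:, k:k + 1]
    beta = np.empty((n, m, 4))
    beta[:, m - 1] = 1.0
    for k in range(m - 2, -1, -1):
        b = (beta[:, k + 1] * _obs_likelihood(model, obs, k + 1)) @ model.transition(k).T
        beta[:, k] = b / scale[:, k + 1:k + 2]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post, np.log(scale).sum(axis=1)


def viterbi(model: InheritanceModel, obs: np.ndarray) -> np.ndarray:
    """Most probable state path per offspring, (n_offspring, m) int8."""
    obs = np.atleast_2d(np.asarray(obs))
    n, m = obs.shape
    with np.errstate(divide="ignore"):
        delta = np.log(0.25 * _obs_likelihood(model, obs, 0))
        psi = np.zeros((n, m, 4), dtype=np.int8)
        for k in range(1, m):
            logT = np.log(model.transition(k - 1))
            cand = delta[:, :, None] + logT[None]
            psi[:, k] = cand.argmax(axis=1)
            delta = cand.max(axis=1) + np.log(_obs_likelihood(model, obs, k))
    path = np.empty((n, m), dtype=np.int8)
    path[:, m - 1] = delta.argmax(axis=1)
    rows = np.arange(n)
    for k in range(m - 2, -1, -1):
        path[:, k] = psi[rows, k + 1, path[:, k + 1]]
    return path


@dataclass
class RecombinationMatrix:
    """Inferred homolog switches per interval (rows) and offspring (columns)."""

    latham: np.ndarray  # (m-1, n) 0/1 switches of the Latham homolog
    moy: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.latham + self.moy

    @property
    def n_offspring(self) -> int:
        return self.latham.shape[1]

    def per_offspring(self) -> np.ndarray:
        return self.total.sum(axis=0)

    def grand_total(self) -> int:
        return int(self.total.sum())


def recombination_matrix(paths: np.ndarray) -> RecombinationMatrix:
    """Switch counts from Viterbi paths (n, m) -> intervals x offspring."""
    u = paths >> 1
    v = paths & 1
    return RecombinationMatrix(
        latham=np.abs(np.diff(u, axis=1)).T.astype(np.int32),
        moy=np.abs(np.diff(v, axis=1)).T.astype(np.int32),
    )


def reconstruct_states(model: InheritanceModel, obs: np.ndarray):
    """Viterbi paths plus the interval x offspring recombination matrix."""
    paths = viterbi(model, obs)
    return paths, recombination_matrix(paths)


def hmm_mean(R: RecombinationMatrix) -> float:
    """Mean inferred recombinations per offspring."""
    if R.n_offspring == 0:
        raise ValueError("no offspring")
    return R.grand_total() / R.n_offspring


def total_recombinations(
    markers: list,
    obs: np.ndarray,
    error_rate: float = 0.01,
    map_function: str = "haldane",
    positions: np.ndarray | None = None,
) -> int:
    model = build_model(markers, error_rate, map_function, positions)
    _, R = reconstruct_states(model, obs)
    return R.grand_total()


def exclusion_report(
    markers: list,
    obs: np.ndarray,
    error_rate: float = 0.01,
    map_function: str = "haldane",
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Recombinations removed by excluding each marker in turn.

    Entry k is total(all markers) - total(without marker k); a large value
    flags a badly scored or misplaced marker.
    """
    if positions is None:
        positions = np.array([m.pos for m in markers], dtype=float)
    base = total_recombinations(markers, obs, error_rate, map_function, positions)
    out = np.empty(len(markers))
    for k in range(len(markers)):
        sub = markers[:k] + markers[k + 1:]
        sub_obs = np.delete(obs, k, axis=1)
        sub_pos = np.delete(positions, k)
        out[k] = base - total_recombinations(sub, sub_obs, error_rate,
                                             map_function, sub_pos)
    return out


def _pairwise_distances(pairwise_r):
    """Complete cM distance matrix from two-point r.

    Uninformative pairs (NaN r) get their distance from the shortest path
    through informative pairs, so adjacent intervals between markers
    heterozygous in different single parents stay finite and sensible.
    """
    from scipy.sparse.csgraph import shortest_path

    D = haldane_d(np.clip(np.nan_to_num(pairwise_r, nan=0.4999), 0.0, 0.4999))
    finite = ~np.isnan(pairwise_r)
    graph = np.where(finite, D, 0.0)
    sp = shortest_path(graph, method="D", directed=False)
    out = np.where(finite, D, sp)
    out[~np.isfinite(out)] = D[~np.isfinite(out)]
    return out


def _positions_for_order(order, dist, fallback_positions):
    """Cumulative cM positions for a candidate order.

    With a pairwise distance matrix the interval lengths are re-estimated
    between the new adjacent markers; otherwise markers keep the original
    (sorted) position slots.
    """
    if dist is None:
        return fallback_positions
    d = np.array([dist[order[i], order[i + 1]] for i in range(len(order) - 1)])
    return np.concatenate([[0.0], np.cumsum(d)])


def improve_order(
    markers: list,
    obs: np.ndarray,
    error_rate: float = 1e-6,
    map_function: str = "haldane",
    pairwise_r: np.ndarray | None = None,
    max_rounds: int = 60,
):
    """Greedy order improvement by adjacent swaps and triplet permutations.

    Each round evaluates every adjacent swap and every non-trivial
    permutation of each marker triplet by the total number of Viterbi
    recombinations over all offspring; the single best reducing move is
    applied and interval distances re-estimated.  Marker exclusions are
    evaluated for the final order and reported, not applied.

    The default move-evaluation error rate is tiny so every discrepant
    call costs recombinations: with a loose error rate the Viterbi path
    can absorb a terminal marker's genuine recombinants as errors, making
    wrong orders look spuriously good.  Markers with many miscalls then
    stand out in the exclusion report instead.

    Returns a dict with the improved marker list, observation matrix,
    positions, applied moves, the per-marker exclusion benefit and the
    before/after recombination totals.
    """
    m = len(markers)
    order = list(range(m))
    # without two-point data, the ordered position slots are kept fixed and
    # markers are permuted through them
    slots = np.sort(np.array([mk.pos for mk in markers], dtype=float))
    dist = _pairwise_distances(pairwise_r) if pairwise_r is not None else None

    def evaluate(o):
        mk = [markers[i] for i in o]
        pos = _positions_for_order(o, dist, slots)
        ob = obs[:, o]
        return total_recombinations(mk, ob, error_rate, map_function, pos)

    best_total = evaluate(order)
    start_total = best_total
    moves = []
    for _ in range(max_rounds):
        best_move = None
        best_val = best_total
        for i in range(m - 1):
            cand = order.copy()
            cand[i], cand[i + 1] = cand[i + 1], cand[i]
            v = evaluate(cand)
            if v < best_val:
                best_val, best_move = v, ("swap", i, cand)
        for i in range(m - 2):
            trip = order[i:i + 3]
            for perm in permutations(trip):
                if perm == tuple(trip):
                    continue
                cand = order[:i] + list(perm) + order[i + 3:]
                v = evaluate(cand)
                if v < best_val:
                    best_val, best_move = v, ("triplet", i, cand)
        if best_move is None:
            break
        kind, i, order = best_move
        moves.append((kind, i, best_val))
        best_total = best_val
    improved = [markers[i] for i in order]
    improved_obs = obs[:, order]
    pos = _positions_for_order(order, dist, slots)
    excl = exclusion_report(improved, improved_obs, error_rate, map_function,
                            positions=pos)
    return {
        "order": order,
        "markers": improved,
        "obs": improved_obs,
        "positions": pos,
        "moves": moves,
        "exclusion_benefit": excl,
        "total_before": start_total,
        "total_after": best_total,
    }


def posterior_grid(
    model: InheritanceModel,
    obs: np.ndarray,
    grid: np.ndarray,
):
    """State posteriors at arbitrary grid positions (pseudo-loci).

    Uninformative pseudo-markers are inserted at the grid positions and the
    forward-backward recursions run over the merged locus list.  Returns
    (n_offspring, len(grid), 4).
    """
    grid = np.asarray(grid, dtype=float)
    obs = np.atleast_2d(np.asarray(obs))
    dummy = PhasedMarker("pseudo", -1, 0.0, ("A", "A"), ("A", "A"), "pseudo")
    pos_all = np.concatenate([model.positions, grid])
    src = np.concatenate([np.arange(model.n_markers), -np.ones(grid.size, dtype=int)])
    sort = np.argsort(pos_all, kind="stable")
    pos_all = pos_all[sort]
    src = src[sort]
    mk_ext = [model.markers[s] if s >= 0 else dummy for s in src]
    obs_ext = np.full((obs.shape[0], len(mk_ext)), MISSING, dtype=obs.dtype)
    real = src >= 0
    obs_ext[:, real] = obs[:, src[real]]
    ext = build_model(mk_ext, model.error_rate, model.map_function, pos_all)
    post, _ = forward_backward(ext, obs_ext)
    # map each grid entry back to its (stable-sorted) slot
    grid_slots = np.flatnonzero(~real)
    return post[:, grid_slots, :]
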