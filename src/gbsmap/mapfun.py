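"""Genetic map functions (cM <-> recombination fraction)."""

from __future__ import annotations

import numpy as np

R_CAP = 0.4999
D_CAP_CM = 1e-6  # lower cap on r for numerical stability when mapping back


def haldane_d(r):
    """Haldane map distance (cM) from recombination fraction."""
    r = np.minimum(np.asarray(r, dtype=float), R_CAP)
    return -50.0 * np.log1p(-2.0 * r)


def haldane_r(d):
    """Recombination fraction between loci d cM apart under Haldane."""
    d = np.asarray(d, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def kosambi_d(r):
    r = np.minimum(np.asarray(r, dtype=float), R_CAP)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_r(d):
    d = np.asarray(d, dtype=float)
    t = np.tanh(2.0 * d / 100.0)
    return 0.5 * t


MAP_FUNCTIONS = {
    "haldane": (haldane_d, haldane_r),
    "kosambi": (kosambi_d, kosambi_r),
}


def get_map_function(name: str):
    """Return (r -> cM, cM -> r) callables for a named map function."""
    try:
        return MAP_FUNCTIONS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown map function: {name!r}") from None
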