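"""Hypergeometric over-representation of screen hits against gene-set collections.

The background universe is the set of genes assayed in the screen (not the
whole genome). For a set with K universe members of which k are hits, among n
hits drawn from a universe of N genes, the upper-tail hypergeometric
probability P(X >= k) measures over-representation; p-values are adjusted
across sets with Benjamini-Hochberg. Gene identifiers match case-insensitively
after whitespace stripping.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeom_test",
    "bh_adjust",
    "enrich",
]


def _norm(g: str) -> str:
    return str(g).strip().upper()


class GeneSetCollection:
    """Named gene sets plus the assayed universe."""

    def __init__(self, sets: dict[str, list[str]], universe: list[str]):
        if len(sets) != len({_norm(n) for n in sets}):
            raise ValueError("gene-set names are not unique")
        self.sets = {name: [_norm(g) for g in members] for name, members in sets.items()}
        self.universe = {_norm(g) for g in universe}
        if not self.universe:
            raise ValueError("universe is empty")

    def trimmed(self) -> dict[str, set]:
        """Sets intersected with the universe."""
        return {name: set(m) & self.universe for name, m in self.sets.items()}


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: tab-separated name, description, members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: need name, description, >=1 member")
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g.strip()]
    return sets


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts hits inside a set of size K when n hits are drawn without
    replacement from a universe of N genes.
    """
    if not (0 <= k <= K <= N and k <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    hits,
    collection: GeneSetCollection,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Over-representation of a hit list against a gene-set collection.

    Sets smaller than ``min_set_size`` after trimming to the universe are
    excluded. Returns one row per retained set with k, K, n, N, p and BH q,
    sorted by (p, set name) for deterministic output.
    """
    hit_set = {_norm(g) for g in hits} & collection.universe
    if not hit_set:
        warnings.warn("empty hit list after trimming to universe", stacklevel=2)
    N = len(collection.universe)
    n = len(hit_set)
    rows = []
    for name, members in collection.trimmed().items():
        K = len(members)
        if K < min_set_size:
            continue
        k = len(members & hit_set)
        rows.append(
            {"set": name, "k": k, "K": K, "n": n, "N": N, "p": hypergeom_test(k, K, n, N)}
        )
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(out):
        out = out.sort_values(by=["p", "set"], kind="mergesort").reset_index(drop=True)
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = pd.Series(dtype=float)
    return out
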