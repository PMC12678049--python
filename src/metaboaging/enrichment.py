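"""Hypergeometric over-representation analysis against GMT gene sets.

For a query set of n proteins drawn from a universe of N, a gene set with
K members in the universe and k members in the query is scored with the
exact upper tail P(X >= k) of Hypergeometric(N, K, n); Bonferroni
correction is applied over the sets tested.  One-sided over-representation
only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pwas import bonferroni


class EnrichmentError(ValueError):
    pass


def read_gmt(path) -> dict:
    """Named gene sets from a GMT file (set name, description, members)."""
    from gseapy.parser import read_gmt as _read_gmt

    return {name: set(members)
            for name, members in _read_gmt(str(path)).items()}


def write_gmt(collection: dict, path, description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(collection):
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
    return path


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact over-representation tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query, collection: dict, universe) -> pd.DataFrame:
    """Per-set overlap counts, exact hypergeometric p and Bonferroni p.

    Sets and the query are restricted to the universe; empty (restricted)
    sets are skipped.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise EnrichmentError("universe is empty")
    if not query:
        raise EnrichmentError("query set is empty")
    if not query <= universe:
        raise EnrichmentError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.items():
        inset = set(members) & universe
        if not inset:
            continue
        k = len(inset & query)
        rows.append({"set": name, "k": k, "K": len(inset), "n": n, "N": N,
                     "p": hypergeom_tail(k, len(inset), n, N)})
    if not rows:
        raise EnrichmentError("no gene set overlaps the universe")
    out = pd.DataFrame(rows).set_index("set").sort_values("p")
    out["p_bonf"] = bonferroni(out["p"].to_numpy())
    return out
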