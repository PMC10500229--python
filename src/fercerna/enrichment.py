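"""Over-representation analysis and pathway activation scoring.

ORA tests each gene set with the upper-tail hypergeometric probability
P(X >= k) of drawing k set members in a query of size n from a universe
of N genes containing K set members, followed by Benjamini-Hochberg
adjustment across the collection.  Significance is flagged on the raw
p-value at 0.05 (both raw and adjusted values are reported).

The activation score is the simple direction-consistency z,

    z = (n_consistent - n_inconsistent) / sqrt(n_consistent + n_inconsistent),

where a gene is consistent when it is up-regulated and annotated
activating, or down-regulated and annotated inhibiting.  A positive z
predicts pathway activation, a negative one inhibition.  This is an
approximation to proprietary activation analyses; it is undefined (and
reported absent) when no annotated gene overlaps the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass(frozen=True)
class GeneSet:
    """One annotated gene set (GMT line), optionally direction-annotated."""

    set_id: str
    description: str
    members: frozenset[str]
    directions: Mapping[str, str] | None = None  # gene -> activating/inhibiting

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        if self.directions:
            bad = set(self.directions.values()) - {"activating", "inhibiting"}
            if bad:
                raise ValueError(f"unknown expected directions: {sorted(bad)}")


def ora(
    query: Iterable[str], universe: Iterable[str], collection: Iterable[GeneSet]
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    The query must be a subset of the universe; gene sets are intersected
    with the universe before counting.  Returns a DataFrame sorted by
    p-value with columns ``set_id, description, k, K, n, N, p_value,
    adjusted_p, significant``.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for gs in collection:
        members = gs.members & universe
        K = len(members)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail.
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        # sf(-1) = 1 gives the k=0 tail convention; clamp underflow into (0, 1]
        p = min(max(p, math.nextafter(0.0, 1.0)), 1.0)
        rows.append((gs.set_id, gs.description, k, K, n, N, p))
    out = pd.DataFrame(
        rows, columns=["set_id", "description", "k", "K", "n", "N", "p_value"]
    )
    if len(out):
        out["adjusted_p"] = bh_adjust(out["p_value"])
        out["significant"] = out["p_value"] < 0.05
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


@dataclass(frozen=True)
class ActivationScore:
    set_id: str
    n_consistent: int
    n_inconsistent: int
    z: float


def activation_z(
    query_directions: Mapping[str, str], gene_set: GeneSet
) -> ActivationScore | None:
    """Direction-consistency activation z-score for one annotated set.

    ``query_directions`` maps genes to observed ``up``/``down``.  Returns
    ``None`` when no direction-annotated set member is in the query
    (the score is undefined there, not zero).
    """
    if not gene_set.directions:
        raise ValueError(f"gene set {gene_set.set_id!r} carries no direction annotations")
    bad = set(query_directions.values()) - {"up", "down"}
    if bad:
        raise ValueError(f"observed directions must be up/down, got {sorted(bad)}")
    n_con = n_inc = 0
    for gene, expected in gene_set.directions.items():
        observed = query_directions.get(gene)
        if observed is None:
            continue
        consistent = (observed == "up") == (expected == "activating")
        if consistent:
            n_con += 1
        else:
            n_inc += 1
    total = n_con + n_inc
    if total == 0:
        return None
    return ActivationScore(
        set_id=gene_set.set_id,
        n_consistent=n_con,
        n_inconsistent=n_inc,
        z=(n_con - n_inc) / math.sqrt(total),
    )
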