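"""Assembly of the ferroptosis-related ceRNA network.

A competing-endogenous-RNA (ceRNA) triad is one lncRNA-miRNA-mRNA axis in
which the lncRNA competes with the mRNA for binding of the shared miRNA.
Candidate axes are assembled by joining lncRNA-miRNA interaction pairs
(starBase-like evidence) with miRNA-mRNA target pairs (the agreement, or
optionally the union, of two target databases), keeping only
differentially expressed miRNAs.  The ceRNA hypothesis then imposes a
direction-consistency rule: the lncRNA and the mRNA must move in the same
direction between case and control, and the miRNA in the opposite one.

The resulting network is a typed tripartite undirected graph with
lnc-mi and mi-mRNA edges only; every edge belongs to at least one triad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

TRIAD_COLUMNS = ["lncrna", "mirna", "mrna", "lnc_dir", "mi_dir", "mrna_dir"]
FRG_ROLES = ("Driver", "Suppressor", "Marker")


def normalize_id(gene: str) -> str:
    """Matching key for gene ids: trimmed and case-folded, no alias lookup."""
    return str(gene).strip().casefold()


def intersect_frgs(de_mrnas: pd.DataFrame, frgs: pd.DataFrame) -> pd.DataFrame:
    """Intersect passing DE-mRNAs with the ferroptosis gene list.

    ``frgs`` has columns ``gene`` and ``role`` (Driver/Suppressor/Marker).
    Returns the DE records whose normalised id is ferroptosis-related,
    with the role attached.  Matching is by exact normalised string; the
    original ids are kept in the output.
    """
    if len(frgs) == 0:
        warnings.warn("empty ferroptosis gene list; no DE-FRGs possible")
        return de_mrnas.iloc[0:0].assign(role=pd.Series(dtype=str))
    bad_roles = set(frgs["role"]) - set(FRG_ROLES)
    if bad_roles:
        raise ValueError(f"unknown FRG roles: {sorted(bad_roles)}")
    passing = de_mrnas[de_mrnas["passes"]].copy()
    role_of = {normalize_id(g): r for g, r in zip(frgs["gene"], frgs["role"])}
    keys = passing["gene"].map(normalize_id)
    keep = keys.isin(role_of)
    out = passing[keep].copy()
    out["role"] = keys[keep].map(role_of)
    return out.reset_index(drop=True)


def _pair_key(df: pd.DataFrame) -> pd.Series:
    return df["source"].map(normalize_id) + "\t" + df["target"].map(normalize_id)


def combine_target_dbs(
    db1: pd.DataFrame, db2: pd.DataFrame, mode: str = "intersection"
) -> pd.DataFrame:
    """Merge two miRNA->mRNA target databases into candidate pairs.

    ``mode="intersection"`` (default) keeps pairs supported by both
    databases, ``"union"`` keeps pairs from either.  Duplicates are
    collapsed; a ``provenance`` column records which databases support
    each pair (comma-joined).
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"mode must be 'intersection' or 'union', got {mode!r}")
    frames = []
    for name, db in (("db1", db1), ("db2", db2)):
        d = db[["source", "target"]].copy()
        if (d["source"].map(normalize_id) == d["target"].map(normalize_id)).any():
            raise ValueError(f"{name} contains self pairs")
        d["provenance"] = name
        frames.append(d.drop_duplicates(subset=["source", "target"]))
    both = pd.concat(frames, ignore_index=True)
    both["_key"] = _pair_key(both)
    grouped = both.groupby("_key", sort=False).agg(
        source=("source", "first"),
        target=("target", "first"),
        provenance=("provenance", lambda s: ",".join(sorted(set(s)))),
        n_db=("provenance", "nunique"),
    )
    if mode == "intersection":
        grouped = grouped[grouped["n_db"] == 2]
    return grouped.drop(columns="n_db").reset_index(drop=True)


def assemble_axes(
    lnc_mi: pd.DataFrame, mi_mrna: pd.DataFrame, de_mirnas: pd.DataFrame
) -> pd.DataFrame:
    """Join lncRNA-miRNA and miRNA-mRNA pairs into candidate axes.

    An axis (l, m, g) exists iff (l, m) is a lnc-mi pair, (m, g) is a
    mi-mRNA pair, and m is a passing DE-miRNA.  miRNAs absent from either
    pair set drop out of the join ("non-common" miRNAs); the output is
    deduplicated on normalised ids.
    """
    de_mi = {
        normalize_id(g)
        for g, ok in zip(de_mirnas["gene"], de_mirnas["passes"])
        if ok
    }
    left = lnc_mi[["source", "target"]].rename(
        columns={"source": "lncrna", "target": "mirna"}
    )
    right = mi_mrna[["source", "target"]].rename(
        columns={"source": "mirna", "target": "mrna"}
    )
    left = left.assign(_mi=left["mirna"].map(normalize_id))
    right = right.assign(_mi=right["mirna"].map(normalize_id))
    left = left[left["_mi"].isin(de_mi)]
    right = right[right["_mi"].isin(de_mi)]
    axes = left.merge(right[["_mi", "mrna"]], on="_mi")[["lncrna", "mirna", "mrna"]]
    axes["_key"] = (
        axes["lncrna"].map(normalize_id)
        + "\t"
        + axes["mirna"].map(normalize_id)
        + "\t"
        + axes["mrna"].map(normalize_id)
    )
    axes = axes.drop_duplicates(subset="_key").drop(columns="_key")
    return axes.reset_index(drop=True)


def filter_directions(axes: pd.DataFrame, de_all: pd.DataFrame) -> pd.DataFrame:
    """Keep axes obeying the ceRNA direction rule; attach directions.

    Rule: sign(log2fc of lncRNA) = sign(log2fc of mRNA) = -sign(log2fc of
    miRNA), all nonzero.  ``de_all`` must hold a DE record (``gene``,
    ``log2fc``) for every axis member, across all three RNA classes.
    Returns a triad table with columns ``lncrna, mirna, mrna, lnc_dir,
    mi_dir, mrna_dir``.
    """
    fc = {normalize_id(g): f for g, f in zip(de_all["gene"], de_all["log2fc"])}
    rows = []
    for l, m, g in axes[["lncrna", "mirna", "mrna"]].itertuples(index=False):
        for member in (l, m, g):
            if normalize_id(member) not in fc:
                raise KeyError(f"no DE record for axis member {member!r}")
        fl, fm, fg = (fc[normalize_id(x)] for x in (l, m, g))
        if fl == 0 or fm == 0 or fg == 0:
            continue
        if (fl > 0) == (fg > 0) and (fl > 0) != (fm > 0):
            rows.append(
                (l, m, g,
                 "up" if fl > 0 else "down",
                 "up" if fm > 0 else "down",
                 "up" if fg > 0 else "down")
            )
    return pd.DataFrame(rows, columns=TRIAD_COLUMNS)


@dataclass
class CeRNANetwork:
    """Typed tripartite undirected ceRNA graph plus its triad list.

    ``graph`` nodes carry ``node_class`` (lncRNA/miRNA/mRNA),
    ``direction`` (up/down) and ``log2fc`` attributes; edges carry
    ``kind`` ("lnc-mi" or "mi-mrna").  ``triads`` is the defining triad
    table (see :data:`TRIAD_COLUMNS`).
    """

    graph: nx.Graph
    triads: pd.DataFrame

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
        for _, data in self.graph.nodes(data=True):
            counts[data["node_class"]] += 1
        return counts

    def node_table(self) -> pd.DataFrame:
        rows = [
            (n, d["node_class"], d["direction"], d["log2fc"])
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["node", "node_class", "direction", "log2fc"])

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["kind"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "kind"])


def build_network(
    triads: pd.DataFrame, log2fc: Mapping[str, float] | None = None
) -> CeRNANetwork:
    """Build the typed network defined by a triad table.

    Nodes are the distinct ids across triads; edges are the lnc-mi and
    mi-mRNA links of each triad (shared edges collapsed).  ``log2fc``
    optionally supplies per-gene effect sizes for the node attributes
    (defaults to 0.0 when absent).
    """
    fc = {normalize_id(k): v for k, v in (log2fc or {}).items()}
    g = nx.Graph()
    for l, m, r, dl, dm, dr in triads[TRIAD_COLUMNS].itertuples(index=False):
        for node, cls, direction in (
            (l, "lncRNA", dl), (m, "miRNA", dm), (r, "mRNA", dr)
        ):
            g.add_node(
                node,
                node_class=cls,
                direction=direction,
                log2fc=fc.get(normalize_id(node), 0.0),
            )
        g.add_edge(l, m, kind="lnc-mi")
        g.add_edge(m, r, kind="mi-mrna")
    return CeRNANetwork(graph=g, triads=triads.reset_index(drop=True))
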