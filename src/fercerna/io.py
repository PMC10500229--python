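"""Readers and writers for every exchange format of the pipeline.

All tabular exchange is tab-separated text with a single header row;
gene ids are opaque strings.  Formats:

* expression matrix: rows = gene ids (first column ``gene``), columns =
  sample ids; companion group file ``sample<TAB>group`` with groups
  ``case``/``control``;
* interaction pairs: ``source<TAB>target``;
* ferroptosis gene list: ``gene<TAB>role`` with role in
  Driver/Suppressor/Marker;
* gene sets: standard GMT (set id, description, member...), plus an
  optional direction sidecar ``set_id<TAB>gene<TAB>expected_direction``;
* network: an edge list (``source, target, kind``) plus a node
  attribute table (``node, node_class, direction, log2fc``), the
  exchange format for graph viewers;
* triads: ``lncrna, mirna, mrna, lnc_dir, mi_dir, mrna_dir``;
* Ct tables: ``sample, group, gene, replicate, ct``;
* ground truth and reports: JSON.

Malformed input (ragged rows, duplicate ids, unknown classes) fails
with the offending file and line number.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .cerna import TRIAD_COLUMNS, CeRNANetwork, FRG_ROLES
from .diffexpr import ExpressionMatrix
from .enrichment import GeneSet
from .simulate import GroundTruth, SimulatedDataset

logger = logging.getLogger("fercerna")


def _read_tsv_rows(path: str | Path, expected_cols: Sequence[str]) -> list[list[str]]:
    """Header-checked TSV rows; ragged rows fail with their line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, expected header {list(expected_cols)}")
    header = lines[0].split("\t")
    if header != list(expected_cols):
        raise ValueError(
            f"{path}:1: expected header {list(expected_cols)}, got {header}"
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(expected_cols):
            raise ValueError(
                f"{path}:{lineno}: expected {len(expected_cols)} fields, got {len(fields)}"
            )
        rows.append(fields)
    return rows


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# -- expression matrices -------------------------------------------------


def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, group_path: str | Path
) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(matrix_path, sep="\t")
    _write_tsv(
        pd.DataFrame({"sample": matrix.groups.index, "group": matrix.groups.values}),
        group_path,
    )


def read_expression(
    matrix_path: str | Path, group_path: str | Path, rna_class: str
) -> ExpressionMatrix:
    values = pd.read_csv(
        matrix_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"{matrix_path}: duplicate gene id {dup!r}")
    groups_rows = _read_tsv_rows(group_path, ["sample", "group"])
    groups = pd.Series({s: g for s, g in groups_rows})
    return ExpressionMatrix(values=values, groups=groups, rna_class=rna_class)


# -- pairs, gene lists ---------------------------------------------------


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(pairs[["source", "target"]], path)


def read_pairs(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv_rows(path, ["source", "target"])
    return pd.DataFrame(rows, columns=["source", "target"])


def write_frgs(frgs: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(frgs[["gene", "role"]], path)


def read_frgs(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv_rows(path, ["gene", "role"])
    for lineno, (gene, role) in enumerate(rows, start=2):
        if role not in FRG_ROLES:
            raise ValueError(f"{path}:{lineno}: unknown FRG role {role!r}")
    return pd.DataFrame(rows, columns=["gene", "role"])


# -- DE tables -----------------------------------------------------------

DE_COLUMNS = ["gene", "rna_class", "log2fc", "p_value", "fdr", "direction", "passes"]


def write_de(de: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(de[DE_COLUMNS], path)


def read_de(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv_rows(path, DE_COLUMNS)
    df = pd.DataFrame(rows, columns=DE_COLUMNS)
    for col in ("log2fc", "p_value", "fdr"):
        df[col] = df[col].astype(float)
    df["passes"] = df["passes"].map({"True": True, "False": False})
    if df["passes"].isna().any():
        raise ValueError(f"{path}: 'passes' must be True/False")
    return df


# -- gene sets (GMT) -----------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs id, description and >=1 member"
            )
        set_id, description, *members = fields
        if set_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        seen.add(set_id)
        members = [m for m in members if m]
        if len(members) == 1:
            logger.warning("%s:%d: gene set %r has a single member", path, lineno, set_id)
        sets.append(GeneSet(set_id=set_id, description=description, members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")


def read_set_directions(path: str | Path) -> dict[str, dict[str, str]]:
    """Direction sidecar: set_id -> {gene: activating/inhibiting}."""
    rows = _read_tsv_rows(path, ["set_id", "gene", "expected_direction"])
    out: dict[str, dict[str, str]] = {}
    for lineno, (set_id, gene, direction) in enumerate(rows, start=2):
        if direction not in ("activating", "inhibiting"):
            raise ValueError(f"{path}:{lineno}: unknown expected direction {direction!r}")
        out.setdefault(set_id, {})[gene] = direction
    return out


# -- triads and networks -------------------------------------------------


def write_triads(triads: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(triads[TRIAD_COLUMNS], path)


def read_triads(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv_rows(path, TRIAD_COLUMNS)
    return pd.DataFrame(rows, columns=TRIAD_COLUMNS)


def write_network(
    network: CeRNANetwork,
    edge_path: str | Path,
    node_path: str | Path,
    triad_path: str | Path | None = None,
) -> None:
    _write_tsv(network.edge_table(), edge_path)
    _write_tsv(network.node_table(), node_path)
    if triad_path is not None:
        write_triads(network.triads, triad_path)


def read_network(
    edge_path: str | Path,
    node_path: str | Path,
    triad_path: str | Path | None = None,
) -> CeRNANetwork:
    edges = _read_tsv_rows(edge_path, ["source", "target", "kind"])
    nodes = _read_tsv_rows(node_path, ["node", "node_class", "direction", "log2fc"])
    g = nx.Graph()
    for lineno, (node, cls, direction, fc) in enumerate(nodes, start=2):
        if cls not in ("lncRNA", "miRNA", "mRNA"):
            raise ValueError(f"{node_path}:{lineno}: unknown node class {cls!r}")
        g.add_node(node, node_class=cls, direction=direction, log2fc=float(fc))
    for lineno, (u, v, kind) in enumerate(edges, start=2):
        for n in (u, v):
            if n not in g:
                raise ValueError(f"{edge_path}:{lineno}: edge references unknown node {n!r}")
        g.add_edge(u, v, kind=kind)
    triads = (
        read_triads(triad_path)
        if triad_path is not None
        else pd.DataFrame(columns=TRIAD_COLUMNS)
    )
    return CeRNANetwork(graph=g, triads=triads)


# -- Ct tables, ground truth, reports ------------------------------------

CT_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]


def write_ct(table: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(table[CT_COLUMNS], path)


def read_ct(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv_rows(path, CT_COLUMNS)
    df = pd.DataFrame(rows, columns=CT_COLUMNS)
    df["replicate"] = df["replicate"].astype(int)
    df["ct"] = df["ct"].astype(float)
    return df


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# -- whole simulated datasets --------------------------------------------

DATASET_FILES = {
    "mrna_matrix": "mrna_expression.tsv",
    "mrna_groups": "mrna_groups.tsv",
    "lncrna_matrix": "lncrna_expression.tsv",
    "lncrna_groups": "lncrna_groups.tsv",
    "mirna_matrix": "mirna_expression.tsv",
    "mirna_groups": "mirna_groups.tsv",
    "frgs": "frgs.tsv",
    "lnc_mi": "lnc_mi_pairs.tsv",
    "mi_mrna_db1": "mi_mrna_db1_pairs.tsv",
    "mi_mrna_db2": "mi_mrna_db2_pairs.tsv",
    "truth": "ground_truth.json",
}


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every file of a simulated study; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in DATASET_FILES.items()}
    write_expression(dataset.mrna, paths["mrna_matrix"], paths["mrna_groups"])
    write_expression(dataset.lncrna, paths["lncrna_matrix"], paths["lncrna_groups"])
    write_expression(dataset.mirna, paths["mirna_matrix"], paths["mirna_groups"])
    write_frgs(dataset.frgs, paths["frgs"])
    write_pairs(dataset.lnc_mi, paths["lnc_mi"])
    write_pairs(dataset.mi_mrna_db1, paths["mi_mrna_db1"])
    write_pairs(dataset.mi_mrna_db2, paths["mi_mrna_db2"])
    write_ground_truth(dataset.truth, paths["truth"])
    return paths


def read_dataset(outdir: str | Path) -> SimulatedDataset:
    outdir = Path(outdir)
    p = {k: outdir / v for k, v in DATASET_FILES.items()}
    return SimulatedDataset(
        mrna=read_expression(p["mrna_matrix"], p["mrna_groups"], "mRNA"),
        lncrna=read_expression(p["lncrna_matrix"], p["lncrna_groups"], "lncRNA"),
        mirna=read_expression(p["mirna_matrix"], p["mirna_groups"], "miRNA"),
        frgs=read_frgs(p["frgs"]),
        lnc_mi=read_pairs(p["lnc_mi"]),
        mi_mrna_db1=read_pairs(p["mi_mrna_db1"]),
        mi_mrna_db2=read_pairs(p["mi_mrna_db2"]),
        truth=read_ground_truth(p["truth"]),
    )
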