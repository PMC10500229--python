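"""Bundled reference tables from a published osteoarthritis ceRNA study.

Two small worked-example inputs ship with the package so that the
screening operations can be exercised against published numbers without
any download:

* the top-5 lncRNA rankings under degree, betweenness and closeness
  centrality of a ferroptosis-related OA ceRNA network, whose top-5
  cross-metric intersection nominates three pivotal lncRNAs
  (AC011511.5, AL358072.1, C9orf139);
* the pivotal-lncRNA sub-network of that study as a triad table.  The
  study reports, per pivotal lncRNA, its competitively bound miRNAs and
  the ferroptosis genes it regulates, but not the individual
  miRNA-to-mRNA assignments; the bundled table is therefore a
  *reconstruction* — the bipartite completion of each lncRNA's partner
  lists.  Node identities, per-class node counts (3 lncRNA, 7 miRNA,
  12 mRNA) and lncRNA degrees are exact; individual mi-mRNA edges are
  completed, so edge and triad totals exceed the published ones.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cerna import TRIAD_COLUMNS


def _data_path(name: str):
    return resources.files("fercerna").joinpath("data", name)


def load_centrality_top5() -> dict[str, dict[str, float]]:
    """Published top-5 lncRNA centrality columns: metric -> {node: value}."""
    with resources.as_file(_data_path("oa_lncrna_centrality_top5.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return {
        metric: dict(zip(sub["node"], sub["value"]))
        for metric, sub in df.groupby("metric", sort=False)
    }


def load_subnetwork_axes() -> pd.DataFrame:
    """Reconstructed pivotal sub-network triad table (see module docstring)."""
    with resources.as_file(_data_path("oa_subnetwork_axes_reconstructed.tsv")) as path:
        return pd.read_csv(path, sep="\t")[TRIAD_COLUMNS]
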