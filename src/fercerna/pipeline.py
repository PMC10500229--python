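"""End-to-end orchestration: DE screen -> FRG intersection -> ceRNA
network -> topology -> (optional) enrichment, with a run report.

The stages can equally be driven one at a time from the CLI or the
library; this module wires them together in the canonical order on
in-memory objects (:func:`analyze`) or on files (:func:`run_pipeline`).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import cerna, diffexpr, enrichment, topology
from . import io as fio
from .cerna import CeRNANetwork
from .diffexpr import DEFAULT_RULES, ExpressionMatrix, ThresholdRule
from .simulate import SimulatedDataset

logger = logging.getLogger("fercerna")


@dataclass
class AnalysisResult:
    """Every intermediate and final artifact of one pipeline run."""

    de: dict[str, pd.DataFrame]  # rna_class -> DE table
    de_frgs: pd.DataFrame
    axes: pd.DataFrame
    triads: pd.DataFrame
    network: CeRNANetwork
    centrality: pd.DataFrame | None
    pivotal: set[str]
    power_law: topology.PowerLawFit | None
    subnetwork: CeRNANetwork | None
    enrichment: pd.DataFrame | None
    report: dict


def analyze(
    mrna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    frgs: pd.DataFrame,
    lnc_mi: pd.DataFrame,
    mi_mrna_db1: pd.DataFrame,
    mi_mrna_db2: pd.DataFrame,
    rules: Mapping[str, ThresholdRule] = DEFAULT_RULES,
    combine_mode: str = "intersection",
    top_k: int = 5,
    closeness: str = "harmonic",
    prior_df: float = 0.0,
    mirna_is_counts: bool = False,
    gene_sets: list[enrichment.GeneSet] | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs.

    Returns all artifacts plus a JSON-serialisable report with the
    headline numbers of each stage (per-class DE counts, the DE-FRG
    up/down split, triad and node counts, the pivotal set, the
    power-law fit and the sub-network composition).
    """
    if mirna_is_counts:
        mirna = ExpressionMatrix(
            values=diffexpr.log2_cpm(mirna.values),
            groups=mirna.groups,
            rna_class="miRNA",
        )
    de = {
        "mRNA": diffexpr.call_de(mrna, rules["mRNA"], prior_df=prior_df),
        "lncRNA": diffexpr.call_de(lncrna, rules["lncRNA"], prior_df=prior_df),
        "miRNA": diffexpr.call_de(mirna, rules["miRNA"], prior_df=prior_df),
    }
    de_frgs = cerna.intersect_frgs(de["mRNA"], frgs)
    de_lnc_ids = set(de["lncRNA"].loc[de["lncRNA"]["passes"], "gene"])
    frg_ids = set(de_frgs["gene"])

    # restrict candidate pairs to DE-lncRNAs and DE-FRGs before the join
    lnc_mi = lnc_mi[lnc_mi["source"].isin(de_lnc_ids)]
    db1 = mi_mrna_db1[mi_mrna_db1["target"].isin(frg_ids)]
    db2 = mi_mrna_db2[mi_mrna_db2["target"].isin(frg_ids)]
    mi_mrna = cerna.combine_target_dbs(db1, db2, mode=combine_mode)

    axes = cerna.assemble_axes(lnc_mi, mi_mrna, de["miRNA"])
    de_all = pd.concat(de.values(), ignore_index=True)
    triads = cerna.filter_directions(axes, de_all)
    fc = dict(zip(de_all["gene"], de_all["log2fc"]))
    network = cerna.build_network(triads, log2fc=fc)

    centrality = None
    pivotal: set[str] = set()
    power_law = None
    subnetwork = None
    if network.graph.number_of_nodes() > 0:
        centrality = topology.centrality_table(network, closeness=closeness)
        pivotal = topology.pivotal_lncrnas(centrality, k=top_k)
        try:
            power_law = topology.fit_power_law(network)
        except ValueError as exc:
            logger.info("power-law fit skipped: %s", exc)
        subnetwork = topology.extract_subnetwork(network, pivotal)

    enrich = None
    if gene_sets is not None and subnetwork is not None:
        sub_mrnas = {
            n for n, d in subnetwork.graph.nodes(data=True) if d["node_class"] == "mRNA"
        }
        universe = set(de["mRNA"]["gene"])
        enrich = enrichment.ora(sub_mrnas, universe, gene_sets)

    report = {
        "de_counts": {cls: int(d["passes"].sum()) for cls, d in de.items()},
        "de_frg_counts": {
            "total": int(len(de_frgs)),
            "up": int((de_frgs["direction"] == "up").sum()),
            "down": int((de_frgs["direction"] == "down").sum()),
        },
        "axis_count": int(len(axes)),
        "triad_count": int(len(triads)),
        "node_class_counts": network.class_counts,
        "pivotal_lncrnas": sorted(pivotal),
        "power_law": (
            {"a": power_law.a, "b": power_law.b, "r_squared": power_law.r_squared}
            if power_law
            else None
        ),
        "subnetwork_class_counts": subnetwork.class_counts if subnetwork else None,
        "subnetwork_triad_count": int(len(subnetwork.triads)) if subnetwork else 0,
        "enriched_sets": (
            int(enrich["significant"].sum()) if enrich is not None and len(enrich) else None
        ),
    }
    return AnalysisResult(
        de=de,
        de_frgs=de_frgs,
        axes=axes,
        triads=triads,
        network=network,
        centrality=centrality,
        pivotal=pivotal,
        power_law=power_law,
        subnetwork=subnetwork,
        enrichment=enrich,
        report=report,
    )


def analyze_dataset(dataset: SimulatedDataset, **kwargs) -> AnalysisResult:
    """:func:`analyze` on the tuple returned by the simulator."""
    return analyze(
        dataset.mrna,
        dataset.lncrna,
        dataset.mirna,
        dataset.frgs,
        dataset.lnc_mi,
        dataset.mi_mrna_db1,
        dataset.mi_mrna_db2,
        **kwargs,
    )


@dataclass
class PipelineConfig:
    """File-level configuration of a pipeline run (plain YAML mapping)."""

    input_dir: str
    output_dir: str
    gmt: str | None = None
    combine_mode: str = "intersection"
    top_k: int = 5
    closeness: str = "harmonic"
    prior_df: float = 0.0
    mirna_is_counts: bool = False
    mrna_min_abs_log2fc: float = 1.0
    lncrna_min_abs_log2fc: float = 1.0
    mirna_min_abs_log2fc: float = 0.5
    max_p: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def rules(self) -> dict[str, ThresholdRule]:
        return {
            "mRNA": ThresholdRule("mRNA", self.mrna_min_abs_log2fc, "fdr", self.max_p),
            "lncRNA": ThresholdRule("lncRNA", self.lncrna_min_abs_log2fc, "raw", self.max_p),
            "miRNA": ThresholdRule("miRNA", self.mirna_min_abs_log2fc, "raw", self.max_p),
        }

    def digest(self) -> str:
        """Fingerprint of the analysis parameters (not artifact paths)."""
        params = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("input_dir", "output_dir", "gmt", "log_level")
        }
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline on the files of ``config.input_dir``.

    Writes every intermediate artifact plus ``report.json`` (headline
    numbers and a manifest with the config hash and seed) under
    ``config.output_dir`` and returns the report.
    """
    logging.basicConfig(level=config.log_level)
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    if not indir.is_dir():
        raise FileNotFoundError(f"input directory {indir} does not exist")
    dataset = fio.read_dataset(indir)
    gene_sets = fio.read_gmt(config.gmt) if config.gmt else None
    result = analyze_dataset(
        dataset,
        rules=config.rules(),
        combine_mode=config.combine_mode,
        top_k=config.top_k,
        closeness=config.closeness,
        prior_df=config.prior_df,
        mirna_is_counts=config.mirna_is_counts,
        gene_sets=gene_sets,
    )
    outdir.mkdir(parents=True, exist_ok=True)
    for cls, de in result.de.items():
        fio.write_de(de, outdir / f"de_{cls.lower()}.tsv")
    fio.write_de(result.de_frgs.drop(columns="role"), outdir / "de_frgs.tsv")
    fio.write_triads(result.triads, outdir / "triads.tsv")
    fio.write_network(
        result.network,
        outdir / "network_edges.tsv",
        outdir / "network_nodes.tsv",
    )
    if result.centrality is not None:
        fio._write_tsv(result.centrality, outdir / "centrality.tsv")
    if result.subnetwork is not None:
        fio.write_network(
            result.subnetwork,
            outdir / "subnetwork_edges.tsv",
            outdir / "subnetwork_nodes.tsv",
            outdir / "subnetwork_triads.tsv",
        )
    if result.enrichment is not None:
        fio._write_tsv(result.enrichment, outdir / "enrichment.tsv")
    report = dict(result.report)
    report["manifest"] = {"config_hash": config.digest(), "seed": config.seed}
    fio.write_json(report, outdir / "report.json")
    return report
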