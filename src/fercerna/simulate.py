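"""Synthetic two-group transcriptome studies with planted ceRNA structure.

The generator emulates the shape of the real inputs of a ferroptosis
ceRNA analysis — three two-condition expression matrices (mRNA, lncRNA,
miRNA) on the log2 scale, a ferroptosis gene list with roles, a
lncRNA-miRNA interaction file and two miRNA-mRNA target databases — and
plants known structure into them so that every downstream stage of the
pipeline can be validated against ground truth:

* *planted triads*: direction-consistent lncRNA-miRNA-mRNA axes whose
  three members are differentially expressed with |log2FC| equal to
  ``effect_log2fc`` in expectation and whose pairs appear in the
  interaction files (miRNA-mRNA pairs in both target databases);
* *hub lncRNAs*: a few lncRNAs planted into several triads each (at
  least twice as many as any other planted lncRNA) over a shared miRNA
  pool — mirroring the ceRNA crosstalk of real pivotal lncRNAs, which
  sponge common miRNAs — so they form a connected core that the
  centrality screen should nominate as pivotal;
* *direction decoys*: axes whose members are all differentially
  expressed and fully wired in the interaction files but whose
  expression directions violate the ceRNA consistency rule — they
  survive every stage except the direction filter;
* *decoy pairs*: random interaction pairs at a configurable density,
  with a configurable overlap fraction between the two target databases.

Expression is simulated directly on the log2 scale with Gaussian noise;
an optional negative-binomial count mode for the miRNA matrix emulates
sequencing-style input (to be transformed with
:func:`fercerna.diffexpr.log2_cpm` before testing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix

Triad = tuple[str, str, str]

#: sign patterns (lnc, mi, mrna) that violate the ceRNA direction rule
_VIOLATING_PATTERNS = [
    (sl, sm, sg)
    for sl in (1, -1)
    for sm in (1, -1)
    for sg in (1, -1)
    if not (sl == sg and sm == -sl)
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults mirror a desk-scale study: a few hundred genes per RNA
    class, the 20-case / 18-control design typical of cartilage mRNA
    cohorts, a strong planted effect of 2 on the log2 scale with
    per-observation noise SD 0.5, and three hub lncRNAs among thirty
    planted triads.
    """

    n_mrna: int = 300
    n_lncrna: int = 150
    n_mirna: int = 100
    n_case: int = 20
    n_control: int = 18
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    n_planted_triads: int = 30
    n_hub_lncrnas: int = 3
    n_direction_decoys: int = 10
    decoy_pair_density: float = 0.01
    db_overlap: float = 0.5
    frg_fraction: float = 0.2
    mirna_counts: bool = False
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.decoy_pair_density <= 1:
            raise ValueError("decoy_pair_density must lie in [0, 1]")
        if not 0 <= self.db_overlap <= 1:
            raise ValueError("db_overlap must lie in [0, 1]")
        if not 0 < self.frg_fraction <= 1:
            raise ValueError("frg_fraction must lie in (0, 1]")
        if min(self.n_planted_triads, self.n_hub_lncrnas, self.n_direction_decoys) < 0:
            raise ValueError("planted counts must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: the answer key for downstream validation."""

    planted_triads: list[Triad]
    decoy_triads: list[Triad]
    planted_directions: dict[str, str]  # gene -> up/down
    hub_lncrnas: list[str]

    def to_dict(self) -> dict:
        return {
            "planted_triads": [list(t) for t in self.planted_triads],
            "decoy_triads": [list(t) for t in self.decoy_triads],
            "planted_directions": self.planted_directions,
            "hub_lncrnas": self.hub_lncrnas,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_triads=[tuple(t) for t in d["planted_triads"]],
            decoy_triads=[tuple(t) for t in d["decoy_triads"]],
            planted_directions=dict(d["planted_directions"]),
            hub_lncrnas=list(d["hub_lncrnas"]),
        )


class SimulatedDataset(NamedTuple):
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    frgs: pd.DataFrame  # gene, role
    lnc_mi: pd.DataFrame  # source (lncRNA), target (miRNA)
    mi_mrna_db1: pd.DataFrame  # source (miRNA), target (mRNA)
    mi_mrna_db2: pd.DataFrame
    truth: GroundTruth


def _allocate_triads(config: SimulationConfig):
    """Split the planted triads between hub and non-hub lncRNAs.

    Every hub receives the same number of triads, q >= 2; every non-hub
    planted lncRNA receives exactly one, so hubs own at least twice as
    many planted triads as any other planted lncRNA.
    """
    t, h = config.n_planted_triads, config.n_hub_lncrnas
    if t == 0:
        return 0, 0
    if h == 0:
        return 0, t
    q_hub = min(max(2, math.ceil(0.6 * t / h)), t // h)
    if q_hub < 2:
        raise ValueError(
            "infeasible configuration: n_planted_triads too small to give "
            f"each of {h} hub lncRNAs at least 2 triads"
        )
    return q_hub, t - h * q_hub


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one full synthetic study; see module docstring.

    Deterministic in ``config.seed``: identical configs yield identical
    outputs, via independent named substreams of one master seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    keys = ("structure", "expr_mrna", "expr_lncrna", "expr_mirna", "pairs", "frg")
    streams = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))
    rng = streams["structure"]

    mrna_ids = np.array([f"G{i:04d}" for i in range(1, config.n_mrna + 1)])
    lnc_ids = np.array([f"LNC{i:04d}" for i in range(1, config.n_lncrna + 1)])
    mi_ids = np.array([f"MIR{i:04d}" for i in range(1, config.n_mirna + 1)])

    q_hub, n_nonhub = _allocate_triads(config)
    n_hub = config.n_hub_lncrnas if q_hub else 0
    n_lnc_needed = n_hub + n_nonhub + config.n_direction_decoys
    t = config.n_planted_triads
    # hubs share one miRNA pool of size q_hub; each non-hub triad gets a
    # fresh miRNA
    n_mi_needed = (q_hub if n_hub else 0) + n_nonhub + config.n_direction_decoys
    n_frg = int(round(config.frg_fraction * config.n_mrna))
    n_mrna_planted = t + config.n_direction_decoys
    if n_lnc_needed > config.n_lncrna:
        raise ValueError(
            f"infeasible configuration: needs {n_lnc_needed} lncRNAs, have {config.n_lncrna}"
        )
    if n_mi_needed > config.n_mirna:
        raise ValueError(
            f"infeasible configuration: needs {n_mi_needed} miRNAs, have {config.n_mirna}"
        )
    if n_mrna_planted > n_frg:
        raise ValueError(
            f"infeasible configuration: {n_mrna_planted} planted mRNAs exceed "
            f"the ferroptosis list size {n_frg}"
        )

    lnc_pick = rng.permutation(lnc_ids)[:n_lnc_needed]
    mi_pick = rng.permutation(mi_ids)[:n_mi_needed]
    mrna_pick = rng.permutation(mrna_ids)[:n_mrna_planted]
    hubs = list(lnc_pick[:n_hub])
    nonhub_lncs = list(lnc_pick[n_hub: n_hub + n_nonhub])
    decoy_lncs = list(lnc_pick[n_hub + n_nonhub:])
    hub_mis = list(mi_pick[:q_hub]) if n_hub else []
    nonhub_mis = list(mi_pick[len(hub_mis): len(hub_mis) + n_nonhub])
    decoy_mis = list(mi_pick[len(hub_mis) + n_nonhub:])
    triad_mrnas = list(mrna_pick[:t])
    decoy_mrnas = list(mrna_pick[t:])

    directions: dict[str, int] = {}
    planted: list[Triad] = []
    mrna_iter = iter(triad_mrnas)
    # Hubs share one miRNA pool (ceRNA crosstalk: pivotal lncRNAs sponge
    # common miRNAs), forming a connected core whose centrality reflects
    # the planted multiplicity; every hub triad still gets a fresh mRNA.
    hub_sign = int(rng.choice([1, -1])) if n_hub else 0
    for hub in hubs:
        directions[hub] = hub_sign
        for mi in hub_mis:
            directions[mi] = -hub_sign
            g = next(mrna_iter)
            directions[g] = hub_sign
            planted.append((hub, mi, g))
    # non-hub planted lncRNAs each own one private triad
    for lnc, mi in zip(nonhub_lncs, nonhub_mis):
        sign = int(rng.choice([1, -1]))
        directions[lnc] = sign
        directions[mi] = -sign
        g = next(mrna_iter)
        directions[g] = sign
        planted.append((lnc, mi, g))

    decoys: list[Triad] = []
    for i in range(config.n_direction_decoys):
        sl, sm, sg = _VIOLATING_PATTERNS[int(rng.integers(len(_VIOLATING_PATTERNS)))]
        lnc, mi, g = decoy_lncs[i], decoy_mis[i], decoy_mrnas[i]
        directions[lnc], directions[mi], directions[g] = sl, sm, sg
        decoys.append((lnc, mi, g))

    frgs = _frg_list(config, streams["frg"], mrna_ids, triad_mrnas + decoy_mrnas, n_frg)
    lnc_mi, db1, db2 = _pair_files(
        config, streams["pairs"], lnc_ids, mi_ids, mrna_ids, planted, decoys
    )

    matrices = {}
    for cls, ids, key in (
        ("mRNA", mrna_ids, "expr_mrna"),
        ("lncRNA", lnc_ids, "expr_lncrna"),
        ("miRNA", mi_ids, "expr_mirna"),
    ):
        counts_mode = config.mirna_counts and cls == "miRNA"
        matrices[cls] = _expression_matrix(
            config, streams[key], ids, directions, cls, counts_mode
        )

    truth = GroundTruth(
        planted_triads=planted,
        decoy_triads=decoys,
        planted_directions={
            g: ("up" if s > 0 else "down") for g, s in directions.items()
        },
        hub_lncrnas=hubs,
    )
    return SimulatedDataset(
        mrna=matrices["mRNA"],
        lncrna=matrices["lncRNA"],
        mirna=matrices["miRNA"],
        frgs=frgs,
        lnc_mi=lnc_mi,
        mi_mrna_db1=db1,
        mi_mrna_db2=db2,
        truth=truth,
    )


def _frg_list(config, rng, mrna_ids, planted_mrnas, n_frg) -> pd.DataFrame:
    planted = list(planted_mrnas)
    others = [g for g in mrna_ids if g not in set(planted)]
    fill = list(rng.permutation(others)[: n_frg - len(planted)])
    genes = planted + fill
    roles = rng.choice(["Driver", "Suppressor", "Marker"], size=len(genes))
    return (
        pd.DataFrame({"gene": genes, "role": roles})
        .sort_values("gene", kind="stable")
        .reset_index(drop=True)
    )


def _sample_pairs(rng, sources, targets, m, exclude: set[tuple[str, str]]):
    """m distinct random (source, target) pairs avoiding ``exclude``."""
    out: list[tuple[str, str]] = []
    seen = set(exclude)
    max_possible = len(sources) * len(targets) - len(exclude)
    m = min(m, max(max_possible, 0))
    while len(out) < m:
        batch = max(2 * (m - len(out)), 16)
        s = rng.choice(sources, size=batch)
        tgt = rng.choice(targets, size=batch)
        for pair in zip(s, tgt):
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
                if len(out) == m:
                    break
    return out


def _pair_files(config, rng, lnc_ids, mi_ids, mrna_ids, planted, decoys):
    planted_lm = list(dict.fromkeys((l, m) for l, m, _ in planted + decoys))
    planted_mg = list(dict.fromkeys((m, g) for _, m, g in planted + decoys))

    m_lm = int(round(config.decoy_pair_density * len(lnc_ids) * len(mi_ids)))
    lm_decoys = _sample_pairs(rng, lnc_ids, mi_ids, m_lm, set(planted_lm))
    lnc_mi = pd.DataFrame(planted_lm + lm_decoys, columns=["source", "target"])

    m_mm = int(round(config.decoy_pair_density * len(mi_ids) * len(mrna_ids)))
    shared_quota = int(round(config.db_overlap * m_mm))
    n_shared_random = max(shared_quota - len(planted_mg), 0)
    n_unique = max(m_mm - shared_quota, 0)
    pool = _sample_pairs(
        rng, mi_ids, mrna_ids, n_shared_random + 2 * n_unique, set(planted_mg)
    )
    shared = planted_mg + pool[:n_shared_random]
    db1_only = pool[n_shared_random: n_shared_random + n_unique]
    db2_only = pool[n_shared_random + n_unique:]
    db1 = pd.DataFrame(shared + db1_only, columns=["source", "target"])
    db2 = pd.DataFrame(shared + db2_only, columns=["source", "target"])
    return lnc_mi, db1, db2


def _expression_matrix(
    config, rng, ids, directions: dict[str, int], rna_class: str, counts_mode: bool
) -> ExpressionMatrix:
    n_genes, n1, n2 = len(ids), config.n_case, config.n_control
    samples = [f"case_{i + 1}" for i in range(n1)] + [
        f"ctrl_{i + 1}" for i in range(n2)
    ]
    groups = pd.Series(["case"] * n1 + ["control"] * n2, index=samples)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    mu = np.tile(baseline[:, None], (1, n1 + n2))
    shift = np.array([directions.get(g, 0) for g in ids], dtype=float)
    mu[:, :n1] += shift[:, None] * config.effect_log2fc
    if counts_mode:
        # sequencing-style counts: NB with mean 2^mu, fixed dispersion
        mean = 2.0 ** mu
        disp = 0.1
        n_param = 1.0 / disp
        p_param = n_param / (n_param + mean)
        values = rng.negative_binomial(n_param, p_param).astype(float)
    else:
        values = mu + rng.normal(0.0, config.noise_sd, size=mu.shape)
    df = pd.DataFrame(values, index=pd.Index(ids, name="gene"), columns=samples)
    return ExpressionMatrix(values=df, groups=groups, rna_class=rna_class)


def simulate_ct_table(
    n_case: int,
    n_control: int,
    true_fold_change: float,
    ct_sd: float,
    seed: int,
    n_replicates: int = 3,
    target: str = "TARGET",
    reference: str = "GAPDH",
) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table in triplicate.

    The generating model puts the case group's target expression at
    ``true_fold_change`` times the control group's, i.e. the case target
    Ct sits log2(fold change) cycles below the control target Ct at
    equal reference levels; per-replicate Gaussian noise of SD ``ct_sd``
    cycles is added to every measured Ct.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one sample per group")
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    if ct_sd < 0:
        raise ValueError("ct_sd must be non-negative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ref_base, delta0 = 18.0, 5.0
    rows = []
    for group, n in (("case", n_case), ("control", n_control)):
        shift = -math.log2(true_fold_change) if group == "case" else 0.0
        for i in range(n):
            sample = f"{group}_{i + 1}"
            for gene, level in ((reference, ref_base), (target, ref_base + delta0 + shift)):
                for rep in range(1, n_replicates + 1):
                    ct = level + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0)
                    rows.append((sample, group, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
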