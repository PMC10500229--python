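"""Differential-expression screening for two-group transcriptome matrices.

The screen is run independently per RNA class (mRNA, lncRNA, miRNA) on
log2-scale expression values with a case-vs-control design (case is the
disease group; all fold changes are oriented case minus control).  Each
class carries its own significance rule:

========  ============  =========  ======
class     |log2FC| >    p column   p <
========  ============  =========  ======
mRNA      1.0           FDR (BH)   0.05
lncRNA    1.0           raw P      0.05
miRNA     0.5           raw P      0.05
========  ============  =========  ======

The per-gene test is a pooled-variance two-sample t-test on the log2
values, optionally with variance shrinkage toward the mean per-gene
variance (``prior_df`` > 0 gives a moderated-t flavour; the default 0 is
the ordinary Student test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale expression with a two-group design.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids, columns are sample ids.
    groups
        Mapping (or Series) sample id -> ``"case"`` / ``"control"``,
        covering every column of ``values``.
    rna_class
        One of ``"mRNA"``, ``"lncRNA"``, ``"miRNA"``.
    """

    values: pd.DataFrame
    groups: pd.Series
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(dict(self.groups))
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise ValueError(f"group labels must be in {GROUPS}, got {bad}")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"need >=2 {g!r} samples, got {(self.groups == g).sum()}")

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])


@dataclass(frozen=True)
class ThresholdRule:
    """Class-specific DE call rule: |log2FC| and raw-P or FDR cutoff."""

    rna_class: str
    min_abs_log2fc: float
    p_type: str  # "raw" or "fdr"
    max_p: float = 0.05

    def __post_init__(self) -> None:
        if self.p_type not in ("raw", "fdr"):
            raise ValueError(f"p_type must be 'raw' or 'fdr', got {self.p_type!r}")


#: Per-class defaults of the screening protocol.
DEFAULT_RULES: Mapping[str, ThresholdRule] = {
    "mRNA": ThresholdRule("mRNA", 1.0, "fdr", 0.05),
    "lncRNA": ThresholdRule("lncRNA", 1.0, "raw", 0.05),
    "miRNA": ThresholdRule("miRNA", 0.5, "raw", 0.05),
}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving.

    Values are monotone-enforced and capped at 1.  Inputs must lie in
    (0, 1]; an empty input yields an empty array.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount, for count-scale input."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return np.log2((counts + pseudocount).div(lib, axis=1) * 1e6)


def _pooled_t(
    case: np.ndarray, control: np.ndarray, prior_df: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled-variance t-test per row; returns (t, p).

    Zero-variance rows: p = 1 when the means agree, else the smallest
    positive float (the difference is then exact in the data).
    """
    n1, n2 = case.shape[1], control.shape[1]
    d = case.mean(axis=1) - control.mean(axis=1)
    s1 = case.var(axis=1, ddof=1)
    s2 = control.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2p = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    if prior_df > 0:
        s2p = (df * s2p + prior_df * s2p.mean()) / (df + prior_df)
        df = df + prior_df
    se = np.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = se == 0
    if zero.any():
        tiny = np.nextafter(0.0, 1.0)
        p = np.where(zero & (d == 0), 1.0, np.where(zero, tiny, p))
        with np.errstate(invalid="ignore"):
            t = np.where(zero, np.where(d == 0, 0.0, np.sign(d) * np.inf), t)
    return t, p


def call_de(
    matrix: ExpressionMatrix,
    rule: ThresholdRule | None = None,
    prior_df: float = 0.0,
) -> pd.DataFrame:
    """Call differential expression for every gene of one matrix.

    Returns a DataFrame with one row per gene and columns ``gene``,
    ``rna_class``, ``log2fc`` (case mean minus control mean), ``p_value``,
    ``fdr`` (BH over all genes of the matrix), ``direction`` (``up`` iff
    log2fc > 0) and ``passes`` (the class threshold rule).
    """
    if rule is None:
        rule = DEFAULT_RULES[matrix.rna_class]
    if rule.rna_class != matrix.rna_class:
        raise ValueError(
            f"rule is for {rule.rna_class!r} but matrix is {matrix.rna_class!r}"
        )
    case = matrix.values[matrix.case_samples].to_numpy(float)
    control = matrix.values[matrix.control_samples].to_numpy(float)
    _, p = _pooled_t(case, control, prior_df=prior_df)
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    fdr = bh_adjust(p)
    chosen = fdr if rule.p_type == "fdr" else p
    passes = (np.abs(log2fc) > rule.min_abs_log2fc) & (chosen < rule.max_p)
    return pd.DataFrame(
        {
            "gene": matrix.values.index,
            "rna_class": matrix.rna_class,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(log2fc > 0, "up", "down"),
            "passes": passes,
        }
    ).reset_index(drop=True)
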