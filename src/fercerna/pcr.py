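"""Relative quantification of qPCR data by the 2^-ddCt method.

Per sample, replicate Ct values are averaged (arithmetic mean of
cycles), the target is normalised against a reference gene
(dCt = Ct_target - Ct_reference), calibrated against the control-group
mean dCt (ddCt = dCt - calibrator), and exponentiated
(fold change = 2^-ddCt).  Group differences are assessed with an
unpaired two-sample t-test, by default on the dCt scale (the additive
scale on which the Gaussian error model is natural) with equal
variances; both choices can be switched.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]


class DdctResult(NamedTuple):
    per_sample: pd.DataFrame
    p_value: float | None


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str = "GAPDH",
    test_scale: str = "delta_ct",
    equal_var: bool = True,
) -> DdctResult:
    """Relative expression of ``target`` vs ``reference`` per sample.

    ``table`` is long-format with columns ``sample, group, gene,
    replicate, ct`` (groups ``case``/``control``).  Returns per-sample
    rows (``sample, group, delta_ct, delta_delta_ct, fold_change``) and
    the unpaired t-test p-value between groups (absent when only one
    group is present).

    ``test_scale`` is ``"delta_ct"`` (default) or ``"fold_change"``;
    ``equal_var=False`` switches to Welch's form.
    """
    missing_cols = [c for c in CT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"Ct table lacks columns {missing_cols}")
    if test_scale not in ("delta_ct", "fold_change"):
        raise ValueError(f"unknown test_scale {test_scale!r}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    bad_groups = set(table["group"]) - {"case", "control"}
    if bad_groups:
        raise ValueError(f"groups must be case/control, got {sorted(bad_groups)}")

    means = (
        table.groupby(["sample", "group", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
        .pivot(index=["sample", "group"], columns="gene", values="ct")
    )
    for gene in (target, reference):
        if gene not in means.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    incomplete = means[[target, reference]].isna().any(axis=1)
    if incomplete.any():
        bad = [s for (s, _g) in means.index[incomplete]]
        raise ValueError(f"samples missing target or reference Ct: {bad}")

    out = means.reset_index()[["sample", "group"]].copy()
    out["delta_ct"] = (means[target] - means[reference]).to_numpy()
    control = out.loc[out["group"] == "control", "delta_ct"]
    if len(control) == 0:
        # single-group (case-only) table: calibrate against the overall mean
        warnings.warn("no control samples; calibrating against the overall mean dCt")
        calibrator = out["delta_ct"].mean()
    else:
        calibrator = control.mean()
    out["delta_delta_ct"] = out["delta_ct"] - calibrator
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])

    case = out.loc[out["group"] == "case"]
    p_value: float | None = None
    if len(case) >= 2 and len(control) >= 2:
        col = "delta_ct" if test_scale == "delta_ct" else "fold_change"
        p_value = float(
            stats.ttest_ind(
                case[col], out.loc[out["group"] == "control", col],
                equal_var=equal_var,
            ).pvalue
        )
    return DdctResult(per_sample=out, p_value=p_value)


def group_summary(result: DdctResult) -> pd.DataFrame:
    """Mean fold change and dCt per group, one row per group."""
    return (
        result.per_sample.groupby("group", sort=False)
        .agg(
            n=("sample", "size"),
            mean_delta_ct=("delta_ct", "mean"),
            mean_fold_change=("fold_change", "mean"),
        )
        .reset_index()
    )
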