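"""qPCR relative expression (2^-ddCt) and pH-stress response statistics.

Relative expression follows the Livak ddCt scheme: per replicate,
``dCt = Ct_target - Ct_reference``; ``ddCt = dCt - mean(dCt of the
calibrator group)``; ``fold = 2**-ddCt``.  The per-group "mean fold" is the
geometric mean of replicate folds (equivalently ``2**-mean(ddCt)``), which
makes the calibrator group's mean fold exactly 1.  Group-vs-control
differences use a two-tailed Welch t-test on the log-scale ddCt values, with
the conventional one/two-star significance labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import _spearman_pvalues

#: pH levels of the stress assay; 6.0 is the untreated control/calibrator.
DEFAULT_GROUPS = (4.0, 5.0, 6.0, 7.0, 8.0)
CONTROL_GROUP = 6.0

QPCR_COLUMNS = ("group", "replicate", "gene_id", "ct_target", "ct_reference")


def stars(p: float) -> str:
    """Significance label: '**' for p <= 1e-2, '*' for p <= 5e-2, else ''."""
    if p <= 1.0e-02:
        return "**"
    if p <= 5.0e-02:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    measure: str  # "fresh_weight" | "expression"
    group: float
    p: float
    stars: str


def relative_expression(
    data: pd.DataFrame, calibrator_group: float = CONTROL_GROUP
) -> pd.DataFrame:
    """Per-replicate 2^-ddCt folds from a long Ct table.

    *data* needs columns group, replicate, gene_id, ct_target, ct_reference.
    Returns the table with delta_ct, ddct and fold columns appended.  Every
    gene must have calibrator-group measurements; missing Ct values are an
    error.
    """
    missing_cols = set(QPCR_COLUMNS) - set(data.columns)
    if missing_cols:
        raise ValueError(f"Ct table missing columns: {sorted(missing_cols)}")
    df = data.copy()
    if df[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct value(s) in table")
    if (df[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    out = []
    for gene, sub in df.groupby("gene_id", sort=True):
        calib = sub.loc[sub["group"] == calibrator_group, "delta_ct"]
        if calib.empty:
            raise ValueError(f"calibrator group missing for gene {gene!r}")
        sub = sub.copy()
        sub["ddct"] = sub["delta_ct"] - calib.mean()
        sub["fold"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def summarize_folds(rel: pd.DataFrame) -> pd.DataFrame:
    """Per gene x group fold summary: geometric mean and sd of log2 fold."""
    def geo_mean(x):
        return float(2.0 ** np.mean(np.log2(x)))

    g = rel.groupby(["gene_id", "group"], sort=True)["fold"]
    return pd.DataFrame(
        {
            "mean_fold": g.apply(geo_mean),
            "sd_log2": g.apply(lambda x: float(np.std(np.log2(x), ddof=1))
                               if len(x) > 1 else 0.0),
            "n": g.size(),
        }
    ).reset_index()


def treatment_significance(
    values_treatment: Sequence[float],
    values_control: Sequence[float],
    measure: str = "expression",
    group: float = math.nan,
) -> GroupComparison:
    """Two-tailed Welch t-test between treatment and control replicates."""
    a = np.asarray(values_treatment, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return GroupComparison(measure=measure, group=group, p=p, stars=stars(p))


def expression_response(
    rel: pd.DataFrame, control_group: float = CONTROL_GROUP
) -> pd.DataFrame:
    """Per gene x treatment-group fold change with Welch significance stars.

    The t-test compares ddCt replicate values (log2 scale) of each treatment
    group against the control group.
    """
    rows = []
    for gene, sub in rel.groupby("gene_id", sort=True):
        ctrl = sub.loc[sub["group"] == control_group, "ddct"].to_numpy()
        for grp, gsub in sub.groupby("group", sort=True):
            if grp == control_group:
                continue
            cmp = treatment_significance(
                gsub["ddct"].to_numpy(), ctrl, measure="expression", group=float(grp)
            )
            rows.append(
                {
                    "gene_id": gene,
                    "group": float(grp),
                    "mean_fold": float(2.0 ** -np.mean(gsub["ddct"])),
                    "p": cmp.p,
                    "stars": cmp.stars,
                }
            )
    return pd.DataFrame(rows)


def fresh_weight_response(
    weights: pd.DataFrame, control_group: float = CONTROL_GROUP
) -> pd.DataFrame:
    """Per-group fresh-weight change vs control (columns group, replicate, grams)."""
    ctrl = weights.loc[weights["group"] == control_group, "grams"].to_numpy()
    rows = []
    for grp, sub in weights.groupby("group", sort=True):
        if grp == control_group:
            continue
        cmp = treatment_significance(
            sub["grams"].to_numpy(), ctrl, measure="fresh_weight", group=float(grp)
        )
        rows.append(
            {
                "group": float(grp),
                "mean_grams": float(sub["grams"].mean()),
                "control_mean_grams": float(ctrl.mean()),
                "p": cmp.p,
                "stars": cmp.stars,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HubCorrelationMatrix:
    gene_ids: list
    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # at alpha
    alpha: float
    constant_genes: list  # profiles with zero variance (rho undefined)


def hub_correlations(
    rel: pd.DataFrame,
    use_group_means: bool = False,
    alpha: float = 5.0e-02,
) -> HubCorrelationMatrix:
    """Spearman correlations among hub-gene fold profiles across pH groups.

    Profiles are the per-replicate folds ordered by (group, replicate)
    (n = groups x replicates), or per-group mean folds when
    *use_group_means* is set.  Significance is flagged at p <= alpha; genes
    with constant profiles are reported with NaN correlations.
    """
    wide = rel.pivot_table(
        index="gene_id", columns=["group", "replicate"], values="fold", sort=True
    )
    if wide.isna().any().any():
        raise ValueError("unbalanced Ct table: every gene needs every "
                         "group x replicate")
    if use_group_means:
        wide = wide.T.groupby(level="group").mean().T
    genes = [str(g) for g in wide.index]
    vals = wide.to_numpy(dtype=float)
    const = [g for g, row in zip(genes, vals) if np.std(row) == 0]
    if const:
        warnings.warn(f"constant fold profile(s): {const}; rho undefined",
                      stacklevel=2)
    rho, p = _spearman_pvalues(vals)
    for i, g in enumerate(genes):
        if g in const:
            rho[i, :] = rho[:, i] = np.nan
            p[i, :] = p[:, i] = np.nan
            rho[i, i] = 1.0
    rho_df = pd.DataFrame(rho, index=genes, columns=genes)
    p_df = pd.DataFrame(p, index=genes, columns=genes)
    return HubCorrelationMatrix(
        gene_ids=genes,
        rho=rho_df,
        p=p_df,
        significant=p_df <= alpha,
        alpha=alpha,
        constant_genes=const,
    )
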