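"""Cistrome-transcriptome integration via the score.absFC statistic.

Differential binding peaks annotated to genes are joined to a
differential-expression table; pairs whose gene passes the DEG thresholds
(-log10 p > 1 and |log2FC| > 0.263 by default) are retained and scored as
score.absFC = peak score x |fold change|. Each record carries a
Loss/Gain x Down/Up group label combining the binding change direction
and the expression direction; per factor and binding direction, a Welch
t-test compares score.absFC between down- and up-regulated genes, which
is how coupling between binding loss and transcriptional repression shows
up (Loss-Down heavier than Loss-Up).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: group label short codes: binding (D=loss, U=gain) . expression (D=down, U=up)
GROUP_CODES = {
    ("loss", "down"): "D.D",
    ("loss", "up"): "D.U",
    ("gain", "down"): "U.D",
    ("gain", "up"): "U.U",
}

DEG_LOGPV = 1.0
DEG_ABS_LFC = 0.263


def filter_degs(
    deg_table: pd.DataFrame,
    logpv_min: float = DEG_LOGPV,
    abs_lfc_min: float = DEG_ABS_LFC,
) -> pd.DataFrame:
    """Significant DEGs: -log10 p > logpv_min and |log2FC| > abs_lfc_min."""
    for col in ("gene", "log2FC", "logPV"):
        if col not in deg_table.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    keep = (deg_table["logPV"] > logpv_min) & (
        deg_table["log2FC"].abs() > abs_lfc_min
    )
    return deg_table[keep].reset_index(drop=True)


def build_integration(
    peak_gene_pairs: pd.DataFrame,
    deg_table: pd.DataFrame,
    factor: str | None = None,
    fc_measure: str = "log2",
    logpv_min: float = DEG_LOGPV,
    abs_lfc_min: float = DEG_ABS_LFC,
    collapse_per_gene: bool = False,
) -> pd.DataFrame:
    """Join annotated peaks to DEGs and compute score.absFC per pair.

    ``peak_gene_pairs`` is the annotation table from
    :func:`synercist.intervals.annotate_to_genes` (needs gene, score,
    direction; a ``factor`` column is used if present, else pass
    ``factor=``). Only pairs whose gene is a DEG survive. The fold-change
    measure is |log2FC| (``fc_measure="log2"``) or linear fold change
    2**|log2FC| (``"linear"``).

    With ``collapse_per_gene=True`` only the highest-scoring peak per
    (factor, gene, binding direction) is kept.
    """
    if fc_measure not in ("log2", "linear"):
        raise ValueError(f"unknown fc_measure {fc_measure!r}")
    pairs = peak_gene_pairs.copy()
    if "factor" not in pairs.columns:
        pairs["factor"] = factor if factor is not None else "unknown"
    if pairs["direction"].isin(["none"]).any() or pairs["direction"].isna().any():
        raise ValueError("every peak must carry a gain/loss direction")
    if (pairs["score"] < 0).any() or pairs["score"].isna().any():
        raise ValueError("every peak must carry a non-negative score")

    degs = filter_degs(deg_table, logpv_min, abs_lfc_min)
    merged = pairs.merge(degs[["gene", "log2FC"]], on="gene", how="inner")
    abs_fc = merged["log2FC"].abs()
    if fc_measure == "linear":
        abs_fc = 2.0 ** abs_fc
    records = pd.DataFrame(
        {
            "gene": merged["gene"],
            "factor": merged["factor"],
            "peak_score": merged["score"],
            "binding_direction": merged["direction"],
            "log2FC": merged["log2FC"],
            "expression_direction": np.where(merged["log2FC"] < 0, "down", "up"),
            "score_absFC": merged["score"] * abs_fc,
        }
    )
    records["group"] = [
        GROUP_CODES[(b, e)]
        for b, e in zip(records["binding_direction"], records["expression_direction"])
    ]
    if collapse_per_gene:
        records = (
            records.sort_values("peak_score", ascending=False, kind="mergesort")
            .groupby(["factor", "gene", "binding_direction"], as_index=False)
            .first()
        )
    return records.sort_values(
        ["factor", "gene", "binding_direction"], kind="mergesort"
    ).reset_index(drop=True)


def group_compare(records: pd.DataFrame, factor: str | None = None) -> pd.DataFrame:
    """Welch t-test of score.absFC between expression directions.

    Within each (factor, binding direction), compares score.absFC of
    down-regulated vs up-regulated genes. Returns per-comparison means,
    the t statistic, p-value and the direction of skew (``"down"`` when
    the down-regulated group has the larger mean). Comparisons with fewer
    than 2 records in either group are skipped with a warning.
    """
    df = records if factor is None else records[records["factor"] == factor]
    rows = []
    for (fac, bdir), grp in df.groupby(["factor", "binding_direction"]):
        down = grp.loc[grp["expression_direction"] == "down", "score_absFC"]
        up = grp.loc[grp["expression_direction"] == "up", "score_absFC"]
        if len(down) < 2 or len(up) < 2:
            warnings.warn(
                f"skipping {fac}/{bdir}: needs >=2 records per expression "
                f"direction (down={len(down)}, up={len(up)})",
                stacklevel=2,
            )
            continue
        t = stats.ttest_ind(down, up, equal_var=False)
        rows.append(
            {
                "factor": fac,
                "binding_direction": bdir,
                "n_down": len(down),
                "n_up": len(up),
                "mean_down": float(down.mean()),
                "mean_up": float(up.mean()),
                "t": float(t.statistic),
                "p": float(t.pvalue),
                "skew": "down" if down.mean() > up.mean() else "up",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "factor",
            "binding_direction",
            "n_down",
            "n_up",
            "mean_down",
            "mean_up",
            "t",
            "p",
            "skew",
        ],
    )
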