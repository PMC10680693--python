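"""Rule-based gene-signature selection and tumor-cohort stratification.

The signature is the union of three rule lists drawn from the integration
records: genes with loss of AR binding and up-regulation; genes with loss
of MYC binding and down-regulation; genes with loss of H3K27ac binding
and down-regulation. Tumors in a genes x tumors Z-score cohort are then
clustered on the signature (Ward linkage, Euclidean distance, k = 2 by
default) and the cluster labels are tested for association with ordinal
per-tumor categories (AR activity score, neuroendocrine score) by a
chi-squared test — Yates-corrected for 2x2 tables, plain Pearson
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

#: the three signature rules: factor, binding direction, expression direction
SIGNATURE_RULES = (
    ("AR", "loss", "up"),
    ("MYC", "loss", "down"),
    ("H3K27ac", "loss", "down"),
)


@dataclass
class SignatureSelection:
    """Per-rule gene lists and their deduplicated union."""

    rule_genes: dict[str, list[str]]
    union: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.union = sorted(set().union(*map(set, self.rule_genes.values())))


def select_signature(
    records: pd.DataFrame,
    rules: tuple[tuple[str, str, str], ...] = SIGNATURE_RULES,
) -> SignatureSelection:
    """Apply the three-rule selection to integration records.

    A gene enters a rule's list when it has at least one record of that
    rule's factor with the rule's binding and expression directions.
    """
    rule_genes = {}
    for factor, bdir, edir in rules:
        mask = (
            (records["factor"] == factor)
            & (records["binding_direction"] == bdir)
            & (records["expression_direction"] == edir)
        )
        rule_genes[f"{factor}-{bdir}-{edir}"] = sorted(set(records.loc[mask, "gene"]))
    return SignatureSelection(rule_genes)


@dataclass
class CohortMatrix:
    """Genes x tumors Z-scores with per-tumor AR and NE score categories."""

    zscores: pd.DataFrame  # index = genes, columns = tumors
    ar_category: pd.Series
    ne_category: pd.Series

    def __post_init__(self) -> None:
        if self.zscores.index.duplicated().any():
            raise ValueError("gene symbols must be unique")
        tumors = list(self.zscores.columns)
        for name, cats in (("AR", self.ar_category), ("NE", self.ne_category)):
            missing = [t for t in tumors if t not in cats.index or pd.isna(cats[t])]
            if missing:
                raise ValueError(f"missing {name} category for tumors {missing[:5]}")

    def write(self, matrix_path, labels_path) -> None:
        self.zscores.to_csv(matrix_path, sep="\t", index_label="gene")
        pd.DataFrame(
            {
                "tumor": self.zscores.columns,
                "AR_category": self.ar_category[self.zscores.columns].values,
                "NE_category": self.ne_category[self.zscores.columns].values,
            }
        ).to_csv(labels_path, sep="\t", index=False)

    @classmethod
    def read(cls, matrix_path, labels_path) -> "CohortMatrix":
        z = pd.read_csv(matrix_path, sep="\t", index_col="gene")
        labels = pd.read_csv(labels_path, sep="\t").set_index("tumor")
        return cls(z, labels["AR_category"], labels["NE_category"])


def cluster_tumors(
    cohort: CohortMatrix,
    genes: list[str],
    k: int = 2,
    method: str = "ward",
    metric: str = "euclidean",
) -> pd.Series:
    """Hierarchical clustering of tumor columns on the signature genes.

    Genes missing from the matrix are dropped with a warning. Returns a
    tumor -> cluster-id (1..k) Series. The partition depends only on the
    pairwise distance matrix, so it is invariant to tumor column order up
    to label renaming.
    """
    n_tumors = cohort.zscores.shape[1]
    if k > n_tumors:
        raise ValueError(f"k={k} exceeds number of tumors {n_tumors}")
    present = [g for g in genes if g in cohort.zscores.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from cohort matrix "
            f"(e.g. {missing[:3]})",
            stacklevel=2,
        )
    if not present:
        raise ValueError("no signature genes present in cohort matrix")
    X = cohort.zscores.loc[present].T.to_numpy(float)  # tumors x genes
    if k == 1:
        labels = np.ones(n_tumors, dtype=int)
    else:
        Z = linkage(pdist(X, metric=metric), method=method)
        labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=cohort.zscores.columns, name="cluster")


def association_test(
    cluster_ids: pd.Series,
    categories: pd.Series,
    correction: str = "auto",
) -> dict:
    """Chi-squared association between cluster labels and tumor categories.

    2x2 tables get Yates' continuity correction (X2 = sum of
    (|O - E| - 0.5)^2 / E with the |O - E| - 0.5 term clamped at 0);
    larger tables use plain Pearson X2. ``correction`` may be "auto"
    (shape-keyed, the default), "yates" or "none". Expected counts of 0
    raise; expected counts below 5 attach a warning string.

    Returns a dict with chi2, df, p, the observed and expected tables,
    and any warning.
    """
    common = cluster_ids.index.intersection(categories.index)
    table = pd.crosstab(cluster_ids[common], categories[common])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"need >=2 clusters and >=2 categories, got table shape {table.shape}"
        )
    observed = table.to_numpy(float)
    expected = stats.contingency.expected_freq(observed)
    if (expected == 0).any():
        raise ValueError("contingency table has expected cell counts of 0")
    warning = None
    if (expected < 5).any():
        warning = "expected cell counts below 5; chi-squared approximation weak"

    if correction == "auto":
        use_yates = table.shape == (2, 2)
    elif correction in ("yates", "none"):
        use_yates = correction == "yates"
    else:
        raise ValueError(f"unknown correction {correction!r}")
    chi2, p, df, _ = stats.chi2_contingency(observed, correction=use_yates)
    return {
        "chi2": float(chi2),
        "df": int(df),
        "p": float(p),
        "observed": table,
        "expected": pd.DataFrame(expected, index=table.index, columns=table.columns),
        "yates": use_yates,
        "warning": warning,
    }
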