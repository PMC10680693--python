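"""Hypergeometric enrichment of interval sets, applied four ways.

One exact upper-tail hypergeometric primitive drives:

* cistrome-vs-cistrome overlap significance within a universe of tested
  windows,
* chromatin-state (ChromHMM) enrichment of differential binding sites,
* coregulator gene-class enrichment of peak-annotated genes,

plus a rank-based co-enrichment scan of a cistrome collection (how often a
factor's datasets appear among the most query-overlapping datasets,
relative to its share of the collection).

All p-values are upper tails, P(X >= k): the probability of seeing at least
the observed overlap when draws are made without replacement from the
universe. ``logp`` columns are -log10(p) with p floored at 1e-320.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .intervals import RegionSet, _build_trees, overlaps

P_FLOOR = 1e-320


def hypergeom_upper(
    overlap: int, query_n: int, target_n: int, universe_n: int, exact: bool = False
):
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts target elements in a draw of ``query_n`` from a universe of
    ``universe_n`` containing ``target_n`` targets. Computed as an exact
    rational tail sum (integer binomials); returns a float unless
    ``exact=True``, which returns the :class:`~fractions.Fraction`.
    """
    k, n, K, N = overlap, query_n, target_n, universe_n
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: target {K}, query {n}, universe {N}")
    if k < 0 or k > min(n, K):
        raise ValueError(f"overlap {k} outside [0, min(query {n}, target {K})]")
    total = math.comb(N, n)
    tail = sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1)
    )
    p = Fraction(tail, total)
    return p if exact else float(p)


def neglog10(p: float) -> float:
    return -math.log10(max(p, P_FLOOR))


@dataclass
class EnrichmentResult:
    """One hypergeometric enrichment row."""

    query_label: str
    target_label: str
    overlap: int
    query_size: int
    target_size: int
    universe_size: int
    p_value: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.overlap > min(self.query_size, self.target_size):
            raise ValueError("overlap exceeds min(query, target)")
        if max(self.query_size, self.target_size) > self.universe_size:
            raise ValueError("counts exceed universe")

    @property
    def logp(self) -> float:
        return neglog10(self.p_value)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def as_row(self) -> dict:
        return {
            "query": self.query_label,
            "target": self.target_label,
            "overlap": self.overlap,
            "query_size": self.query_size,
            "target_size": self.target_size,
            "universe_size": self.universe_size,
            "p": self.p_value,
            "logp": self.logp,
            "significant": self.significant,
        }


# ---------------------------------------------------------------------------
# Cistrome-vs-cistrome overlap significance
# ---------------------------------------------------------------------------

def overlap_significance(
    a: RegionSet, b: RegionSet, universe: RegionSet, min_bp: int = 1
) -> EnrichmentResult:
    """Significance of the overlap of two region sets within a universe.

    Universe regions are the draws: those hit (>= min_bp) by *a* form the
    query, those hit by *b* the targets, and the overlap is the universe
    regions hit by both. The universe should be the deduplicated union of
    all windows tested across the compared conditions (see
    :func:`synercist.intervals.merge_regions`); the definition used is
    recorded in the result labels.
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    hit_a = set(overlaps(universe, a, min_bp)["index_a"])
    hit_b = set(overlaps(universe, b, min_bp)["index_a"])
    both = hit_a & hit_b
    p = hypergeom_upper(len(both), len(hit_a), len(hit_b), len(universe))
    return EnrichmentResult(
        a.label, b.label, len(both), len(hit_a), len(hit_b), len(universe), p
    )


def pairwise_overlap_significance(
    sets: list[RegionSet], universe: RegionSet, min_bp: int = 1
) -> pd.DataFrame:
    """Overlap significance for every unordered pair of sets."""
    rows = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            rows.append(
                overlap_significance(sets[i], sets[j], universe, min_bp).as_row()
            )
    return pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ChromHMM state enrichment
# ---------------------------------------------------------------------------

def chromhmm_enrichment(
    regions: dict[tuple[str, str], RegionSet],
    segmentation: RegionSet,
    min_bp: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Chromatin-state enrichment of differential sites, per factor/direction.

    ``regions`` maps ``(factor, direction)`` to the differential sites of
    that factor with that change direction. The segmentation is a
    state-labeled RegionSet (state in the ``name`` field) whose segments
    must not overlap one another.

    For each state the universe is all segmentation regions (N), the
    targets the segments of that state (K), the draws the query regions
    (n), and the successes the query regions intersecting the state by
    >= ``min_bp`` (k); p = P(X >= k) upper tail.

    Returns a table with columns ChromHMM, ChIP, Enrichment, overlap,
    query_size, state_size, universe_size, p, logPval, Threshold, sorted by
    descending logPval.
    """
    seg_pairs = overlaps(segmentation, segmentation)
    if (seg_pairs["index_a"] != seg_pairs["index_b"]).any():
        raise ValueError("segmentation states overlap one another")
    states = sorted({iv.name for iv in segmentation})
    n_total = len(segmentation)
    state_sizes = {
        s: sum(1 for iv in segmentation if iv.name == s) for s in states
    }
    seg_by_state = {
        s: RegionSet(s, [iv for iv in segmentation if iv.name == s], segmentation.genome)
        for s in states
    }
    rows = []
    for (factor, direction), rset in sorted(regions.items()):
        n_query = len(rset)
        for state in states:
            k = len(set(overlaps(rset, seg_by_state[state], min_bp)["index_a"]))
            k = min(k, state_sizes[state], n_query)
            p = hypergeom_upper(k, n_query, state_sizes[state], n_total)
            rows.append(
                {
                    "ChromHMM": state,
                    "ChIP": factor,
                    "Enrichment": direction,
                    "overlap": k,
                    "query_size": n_query,
                    "state_size": state_sizes[state],
                    "universe_size": n_total,
                    "p": float(p),
                    "logPval": neglog10(p),
                    "Threshold": "Significant" if p < alpha else "NS",
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["logPval", "ChromHMM", "ChIP", "Enrichment"],
                     ascending=[False, True, True, True], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Coregulator gene-class enrichment
# ---------------------------------------------------------------------------

def gene_class_enrichment(
    annotated: pd.DataFrame,
    gene_classes: dict[str, str],
    universe_genes: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-class enrichment of peak-annotated genes, one row per class.

    ``annotated`` is the peak:gene table from
    :func:`synercist.intervals.annotate_to_genes` (columns ``gene`` and
    ``distance`` are used); ``gene_classes`` maps gene symbol to class
    label. Per class: hypergeometric upper tail of |hit genes in class|
    draws of |hit genes| from a universe of |universe| with |class| targets.
    The ``closest_member`` column reports the class member nearest any
    query region.
    """
    universe = sorted(set(universe_genes))
    universe_set = set(universe)
    hits = sorted(set(annotated["gene"]) & universe_set)
    if len(set(annotated["gene"]) - universe_set) > 0:
        missing = sorted(set(annotated["gene"]) - universe_set)
        raise ValueError(f"annotated genes outside universe: {missing[:5]}")
    classes = sorted(set(gene_classes.values()))
    best_dist = annotated.groupby("gene")["distance"].min()
    rows = []
    for cls in classes:
        members = {g for g in universe if gene_classes.get(g) == cls}
        k = len(set(hits) & members)
        p = hypergeom_upper(k, len(hits), len(members), len(universe))
        hit_members = sorted(set(hits) & members)
        closest = (
            min(hit_members, key=lambda g: (best_dist[g], g)) if hit_members else ""
        )
        rows.append(
            {
                "class": cls,
                "overlap": k,
                "n_hits": len(hits),
                "class_size": len(members),
                "universe_size": len(universe),
                "p": float(p),
                "logp": neglog10(p),
                "significant": p < alpha,
                "closest_member": closest,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cistrome-collection co-enrichment scan
# ---------------------------------------------------------------------------

@dataclass
class CistromeCollection:
    """A collection of reference binding datasets with a factor census."""

    datasets: list[tuple[str, str, str, RegionSet]]  # (id, factor, tissue, regions)
    factor_census: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [d[0] for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset ids must be unique")
        for did, _, _, rset in self.datasets:
            if len(rset) == 0:
                raise ValueError(f"dataset {did} has no regions")
        if not self.factor_census:
            census: dict[str, int] = {}
            for _, factor, _, _ in self.datasets:
                census[factor] = census.get(factor, 0) + 1
            self.factor_census = census

    def __len__(self) -> int:
        return len(self.datasets)


def load_collection(manifest_path, bed_dir) -> CistromeCollection:
    """Load a cistrome collection from a manifest TSV plus a BED directory.

    The manifest needs columns dataset_id, factor, tissue; each dataset's
    regions live in ``<bed_dir>/<dataset_id>.bed``.
    """
    import os

    from .intervals import read_bed

    manifest = pd.read_csv(manifest_path, sep="\t")
    for col in ("dataset_id", "factor", "tissue"):
        if col not in manifest.columns:
            raise ValueError(f"collection manifest missing column {col!r}")
    datasets = []
    for _, row in manifest.iterrows():
        path = os.path.join(str(bed_dir), f"{row.dataset_id}.bed")
        datasets.append(
            (str(row.dataset_id), str(row.factor), str(row.tissue),
             read_bed(path, label=str(row.dataset_id)))
        )
    return CistromeCollection(datasets)


def coenrichment_scan(
    query: RegionSet,
    collection: CistromeCollection,
    top_n: int = 200,
    fc_threshold: float = 1.2,
    tissue_filter: str | None = None,
    min_bp: int = 1,
) -> pd.DataFrame:
    """Rank collection datasets by query overlap; summarize per factor.

    Each dataset is scored by the number of query regions it overlaps,
    divided by the square root of its region count (a size normalization
    that preserves rank behavior for like-sized datasets). Datasets are
    ranked by descending score (ties by dataset id). Per factor the
    observed proportion is (datasets of that factor in the top ``top_n``) /
    (total datasets of that factor); the background is ``top_n`` /
    collection size; the factor is called co-enriched when observed /
    background exceeds ``fc_threshold``.

    With ``tissue_filter`` the scan is restricted to datasets carrying that
    tissue tag and the mean overlap score per factor is reported instead of
    the census-based fold change.
    """
    datasets = collection.datasets
    if tissue_filter is not None:
        datasets = [d for d in datasets if d[2] == tissue_filter]
        if not datasets:
            raise ValueError(f"no datasets with tissue tag {tissue_filter!r}")
    if tissue_filter is None and top_n > len(datasets):
        raise ValueError(f"top_n {top_n} exceeds collection size {len(datasets)}")

    scored = []
    for did, factor, tissue, rset in datasets:
        if factor not in collection.factor_census:
            raise ValueError(f"factor census missing factor {factor!r}")
        n_hit = len(set(overlaps(query, rset, min_bp)["index_a"]))
        scored.append((did, factor, tissue, n_hit / math.sqrt(len(rset))))
    scored.sort(key=lambda t: (-t[3], t[0]))

    if tissue_filter is not None:
        df = pd.DataFrame(scored, columns=["dataset", "factor", "tissue", "score"])
        out = (
            df.groupby("factor")["score"]
            .agg(mean_score="mean", n_datasets="size")
            .reset_index()
            .sort_values(["mean_score", "factor"], ascending=[False, True],
                         kind="mergesort")
            .reset_index(drop=True)
        )
        return out

    top = scored[:top_n]
    counts: dict[str, int] = {}
    for _, factor, _, _ in top:
        counts[factor] = counts.get(factor, 0) + 1
    background = top_n / len(datasets)
    rows = []
    for factor in sorted(collection.factor_census):
        total = collection.factor_census[factor]
        observed = counts.get(factor, 0) / total
        fc = observed / background
        rows.append(
            {
                "factor": factor,
                "n_in_top": counts.get(factor, 0),
                "n_total": total,
                "observed_prop": observed,
                "background_prop": background,
                "fold_change": fc,
                "co_enriched": fc > fc_threshold,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["fold_change", "factor"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
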