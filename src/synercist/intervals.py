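"""Genomic-interval engine: BED I/O, overlaps, Venn partitioning, gene annotation.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` of length ``end - start``. ``[0, 100)`` and ``[100, 150)``
do not overlap; ``[0, 100)`` and ``[99, 150)`` overlap by 1 bp.

Strand is ignored: cistrome peaks and accessibility regions are unstranded.
The sixth BED column, when present, carries the change-direction label
(``gain`` / ``loss`` / ``none``) instead of a strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

DIRECTIONS = ("gain", "loss", "none")
GENE_CLASSES = ("CoA", "CoR", "Mixed", "TF", "NR", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """One region: ``chrom:[start, end)`` with score, direction and name."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    direction: str = "none"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class RegionSet:
    """A labeled collection of intervals over a named genome.

    Intervals are kept in canonical (chrom, start, end, name) order so that
    equal sets compare equal and all outputs are deterministic.
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    genome: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom not in self.genome:
                    raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > self.genome[iv.chrom]:
                    raise ValueError(
                        f"interval [{iv.start}, {iv.end}) exceeds length of "
                        f"{iv.chrom} ({self.genome[iv.chrom]})"
                    )
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def subset(self, direction: str, label: str | None = None) -> "RegionSet":
        """Regions with the given change direction."""
        return RegionSet(
            label or f"{self.label}.{direction}",
            [iv for iv in self.intervals if iv.direction == direction],
            self.genome,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "direction": [iv.direction for iv in self.intervals],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene: symbol, TSS, span and functional class label.

    Class labels follow the coregulator vocabulary: CoA (coactivator),
    CoR (corepressor), Mixed (dual-function coregulator), TF (transcription
    factor), NR (nuclear receptor), other.
    """

    symbol: str
    chrom: str
    tss: int
    start: int
    end: int
    gene_class: str = "other"

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(
                f"gene class must be one of {GENE_CLASSES}, got {self.gene_class!r}"
            )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path, label: str | None = None, genome: dict[str, int] | None = None) -> RegionSet:
    """Read BED3/BED4/BED5/BED6 into a :class:`RegionSet`.

    Column 4 is the region name, column 5 the score, column 6 the change
    direction (``gain``/``loss``/``none``; ``.``, ``+`` and ``-`` are read
    as ``none``).
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 0.0
            direction = "none"
            if len(parts) > 5 and parts[5] in ("gain", "loss"):
                direction = parts[5]
            intervals.append(GenomicInterval(chrom, start, end, score, direction, name))
    import os

    return RegionSet(label or os.path.basename(str(path)), intervals, genome)


def write_bed(regions: RegionSet, path) -> None:
    """Write a RegionSet as BED6 (direction in the strand column)."""
    with open(path, "w") as fh:
        for iv in regions.intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score!r}\t{iv.direction}\n"
            )


def read_gene_models(path) -> list[GeneModel]:
    """Gene models from TSV with columns symbol, chrom, tss, start, end, class."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(r.symbol, r.chrom, int(r.tss), int(r.start), int(r.end), r["class"])
        for _, r in df.iterrows()
    ]


def write_gene_models(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "symbol": [g.symbol for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "class": [g.gene_class for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Overlap machinery
# ---------------------------------------------------------------------------

def _build_trees(regions: RegionSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, iv in enumerate(regions.intervals):
        trees[iv.chrom].addi(iv.start, iv.end, idx)
    return trees


def overlaps(a: RegionSet, b: RegionSet, min_bp: int = 1) -> pd.DataFrame:
    """All pairs (region of *a*, region of *b*) intersecting by >= *min_bp*.

    Returns a frame with the indices of both regions in their canonical
    orders plus the overlap length in bp. Half-open semantics: touching
    intervals do not overlap.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    trees = _build_trees(b)
    rows = []
    for ia, iv in enumerate(a.intervals):
        for hit in sorted(trees[iv.chrom].overlap(iv.start, iv.end)):
            jb = hit.data
            olen = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if olen >= min_bp:
                rows.append((ia, jb, olen))
    return pd.DataFrame(rows, columns=["index_a", "index_b", "overlap_bp"]).astype(int)


def venn_partition(
    sets: list[RegionSet], min_bp: int = 1, max_sets: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every region of every set to a Venn membership class.

    A region's class is the sorted ``&``-joined list of set labels it
    overlaps (always including its own set), e.g. ``"AR&MYC"``. With *k*
    sets there are at most ``2**k - 1`` classes (15 for k = 4). A region
    overlapping several regions of another set still counts once.

    Returns ``(membership, counts)``: per-region class assignments and a
    per-source-set class count table. Counts per source set sum to that
    set's region count.
    """
    if not 2 <= len(sets) <= max_sets:
        raise ValueError(
            f"venn_partition takes 2..{max_sets} sets, got {len(sets)}"
        )
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("region set labels must be unique")
    trees = {s.label: _build_trees(s) for s in sets}
    rows = []
    for s in sets:
        for idx, iv in enumerate(s.intervals):
            members = {s.label}
            for other in sets:
                if other.label == s.label:
                    continue
                for hit in trees[other.label][iv.chrom].overlap(iv.start, iv.end):
                    if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp:
                        members.add(other.label)
                        break
            cls = "&".join(sorted(members))
            rows.append((s.label, idx, iv.name, cls))
    membership = pd.DataFrame(rows, columns=["set", "index", "name", "venn_class"])
    counts = (
        membership.groupby(["set", "venn_class"]).size().rename("count").reset_index()
    )
    return membership, counts


def annotate_to_genes(
    regions: RegionSet,
    genes: list[GeneModel],
    window: int = 100_000,
    mode: str = "all-in-window",
    use_gene_body: bool = False,
) -> pd.DataFrame:
    """Annotate regions to genes within *window* bp.

    Distance is measured from the region edge to the gene TSS (0 if the TSS
    falls inside the region); with ``use_gene_body=True`` the distance is to
    the gene span instead. ``mode="all-in-window"`` emits every gene within
    the window; ``mode="nearest"`` the single closest gene (ties broken by
    alphabetical symbol), still subject to the window.

    Returns columns region_index, region_name, chrom, start, end, score,
    direction, gene, gene_class, distance.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if mode not in ("all-in-window", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)

    def distance(iv: GenomicInterval, g: GeneModel) -> int:
        # region edge to TSS point (or to the gene span), 0 when inside
        if use_gene_body:
            lo, hi = g.start, g.end - 1
        else:
            lo = hi = g.tss
        return max(iv.start - hi, lo - (iv.end - 1), 0)

    rows = []
    for idx, iv in enumerate(regions.intervals):
        candidates = []
        for g in by_chrom.get(iv.chrom, ()):
            d = distance(iv, g)
            if d <= window:
                candidates.append((d, g.symbol, g))
        if not candidates:
            continue
        if mode == "nearest":
            candidates = [min(candidates, key=lambda t: (t[0], t[1]))]
        else:
            candidates.sort(key=lambda t: (t[0], t[1]))
        for d, _, g in candidates:
            rows.append(
                (
                    idx,
                    iv.name,
                    iv.chrom,
                    iv.start,
                    iv.end,
                    iv.score,
                    iv.direction,
                    g.symbol,
                    g.gene_class,
                    d,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_index",
            "region_name",
            "chrom",
            "start",
            "end",
            "score",
            "direction",
            "gene",
            "gene_class",
            "distance",
        ],
    )


def genome_bins(genome: dict[str, int], width: int, label: str = "bins") -> RegionSet:
    """Tile a genome into fixed-width bins (the last partial bin dropped).

    Used as the universe of tested windows for overlap-significance tests
    when the full set of tested windows is not available.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    intervals = [
        GenomicInterval(chrom, i * width, (i + 1) * width)
        for chrom in sorted(genome)
        for i in range(genome[chrom] // width)
    ]
    return RegionSet(label, intervals, genome)


def merge_regions(sets: list[RegionSet], label: str = "merged") -> RegionSet:
    """Union of all regions across sets, merging any that overlap or touch.

    Used to build the deduplicated universe of tested windows for
    overlap-significance tests.
    """
    genome = next((s.genome for s in sets if s.genome is not None), None)
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for s in sets:
        for iv in s.intervals:
            by_chrom[iv.chrom].append((iv.start, iv.end))
    merged = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s0, e0 in spans[1:]:
            if s0 <= cur_e:
                cur_e = max(cur_e, e0)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s0, e0
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return RegionSet(label, merged, genome)
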