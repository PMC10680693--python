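"""Interval engine: BED I/O, overlaps, Venn classes, gene annotation."""

import numpy as np
import pytest

from synercist.intervals import (
    GeneModel,
    GenomicInterval,
    RegionSet,
    annotate_to_genes,
    genome_bins,
    merge_regions,
    overlaps,
    read_bed,
    venn_partition,
    write_bed,
)

from conftest import GENOME, random_region_set


# --- brute-force oracles (kept independent of the implementation) ----------

def brute_overlap_pairs(a, b, min_bp=1):
    pairs = set()
    for i, x in enumerate(a.intervals):
        for j, y in enumerate(b.intervals):
            if x.chrom == y.chrom:
                o = min(x.end, y.end) - max(x.start, y.start)
                if o >= min_bp:
                    pairs.add((i, j))
    return pairs


def brute_venn_class(iv, own_label, sets, min_bp=1):
    members = {own_label}
    for s in sets:
        if s.label == own_label:
            continue
        for y in s.intervals:
            if iv.chrom == y.chrom and min(iv.end, y.end) - max(iv.start, y.start) >= min_bp:
                members.add(s.label)
                break
    return "&".join(sorted(members))


def brute_annotate(regions, genes, window, mode):
    out = []
    for idx, iv in enumerate(regions.intervals):
        cands = []
        for g in genes:
            if g.chrom != iv.chrom:
                continue
            d = max(iv.start - g.tss, g.tss - (iv.end - 1), 0)
            if d <= window:
                cands.append((d, g.symbol))
        cands.sort()
        if mode == "nearest" and cands:
            cands = cands[:1]
        out.extend((idx, sym, d) for d, sym in cands)
    return set(out)


class TestInterval:
    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, direction="sideways")

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            RegionSet("x", [GenomicInterval("chr1", 0, 2_000_000)], GENOME)


class TestBedIO:
    def test_round_trip_canonical(self, tmp_path, rng):
        rs = random_region_set(rng, 50, "rt")
        path = tmp_path / "x.bed"
        write_bed(rs, path)
        back = read_bed(path, label="rt", genome=GENOME)
        assert back.intervals == rs.intervals

    def test_minimal_bed3(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("chr1\t0\t100\n")
        rs = read_bed(path)
        assert rs.intervals[0].start == 0 and rs.intervals[0].end == 100

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\nchr1\tx\t5\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(path)

    def test_inverted_coordinates_rejected(self, tmp_path):
        path = tmp_path / "inv.bed"
        path.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="start"):
            read_bed(path)


class TestOverlaps:
    def test_half_open_boundaries(self):
        a = RegionSet("a", [GenomicInterval("chr1", 0, 100)], GENOME)
        touch = RegionSet("b", [GenomicInterval("chr1", 100, 150)], GENOME)
        graze = RegionSet("b", [GenomicInterval("chr1", 99, 150)], GENOME)
        assert overlaps(a, touch).empty
        hit = overlaps(a, graze)
        assert len(hit) == 1 and hit.loc[0, "overlap_bp"] == 1

    def test_min_bp_validation(self):
        a = RegionSet("a", [GenomicInterval("chr1", 0, 100)], GENOME)
        with pytest.raises(ValueError):
            overlaps(a, a, min_bp=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("min_bp", [1, 50])
    def test_matches_brute_force(self, seed, min_bp):
        rng = np.random.default_rng(seed)
        a = random_region_set(rng, 80, "a")
        b = random_region_set(rng, 80, "b")
        got = {tuple(t) for t in overlaps(a, b, min_bp)[["index_a", "index_b"]].itertuples(index=False)}
        assert got == brute_overlap_pairs(a, b, min_bp)

    def test_symmetric(self, rng):
        a = random_region_set(rng, 60, "a")
        b = random_region_set(rng, 60, "b")
        ab = {tuple(t) for t in overlaps(a, b)[["index_a", "index_b"]].itertuples(index=False)}
        ba = {tuple(t)[::-1] for t in overlaps(b, a)[["index_a", "index_b"]].itertuples(index=False)}
        assert ab == ba


class TestVennPartition:
    def test_disjoint_sets_single_classes(self):
        a = RegionSet("A", [GenomicInterval("chr1", 0, 100)], GENOME)
        b = RegionSet("B", [GenomicInterval("chr1", 200, 300)], GENOME)
        membership, counts = venn_partition([a, b])
        assert set(membership["venn_class"]) == {"A", "B"}

    def test_identical_sets_all_shared(self):
        ivs = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(5)]
        a = RegionSet("A", ivs, GENOME)
        b = RegionSet("B", list(ivs), GENOME)
        membership, _ = venn_partition([a, b])
        assert set(membership["venn_class"]) == {"A&B"}

    def test_counts_conserved_and_match_oracle(self, rng):
        sets = [random_region_set(rng, 60, lbl) for lbl in "ABC"]
        membership, counts = venn_partition(sets)
        for s in sets:
            assert counts[counts["set"] == s.label]["count"].sum() == len(s)
        for _, row in membership.iterrows():
            s = next(x for x in sets if x.label == row["set"])
            iv = s.intervals[row["index"]]
            assert row["venn_class"] == brute_venn_class(iv, s.label, sets)

    def test_set_count_guard(self):
        a = RegionSet("A", [GenomicInterval("chr1", 0, 10)], GENOME)
        with pytest.raises(ValueError):
            venn_partition([a])
        with pytest.raises(ValueError):
            venn_partition([RegionSet(l, [GenomicInterval("chr1", 0, 10)], GENOME)
                            for l in "ABCDE"])


class TestAnnotateToGenes:
    GENES = [
        GeneModel("ALPHA", "chr1", 100_000, 100_000, 120_000, "TF"),
        GeneModel("BETA", "chr1", 400_000, 400_000, 420_000, "CoA"),
        GeneModel("GAMMA", "chr2", 100_000, 100_000, 120_000, "other"),
    ]

    def test_window_inclusion_and_distance(self):
        regions = RegionSet("r", [GenomicInterval("chr1", 50_000, 50_200)], GENOME)
        pairs = annotate_to_genes(regions, self.GENES, window=100_000)
        assert list(pairs["gene"]) == ["ALPHA"]
        # distance from region end (exclusive) to TSS point
        assert pairs.loc[0, "distance"] == 100_000 - (50_200 - 1)

    def test_outside_window_empty(self):
        regions = RegionSet("r", [GenomicInterval("chr1", 600_000, 600_100)], GENOME)
        pairs = annotate_to_genes(regions, self.GENES, window=100_000)
        assert pairs.empty

    def test_nearest_tie_alphabetical(self):
        genes = [
            GeneModel("ZED", "chr1", 1000, 1000, 2000, "other"),
            GeneModel("ACE", "chr1", 5000, 5000, 6000, "other"),
        ]
        # region equidistant from both TSS
        regions = RegionSet("r", [GenomicInterval("chr1", 2999, 3002)], GENOME)
        pairs = annotate_to_genes(regions, genes, window=10_000, mode="nearest")
        assert list(pairs["gene"]) == ["ACE"]

    @pytest.mark.parametrize("mode", ["all-in-window", "nearest"])
    def test_matches_exhaustive_scan(self, rng, mode):
        regions = random_region_set(rng, 50, "r")
        genes = []
        for i in range(40):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            tss = int(rng.integers(0, GENOME[chrom] - 20_000))
            genes.append(GeneModel(f"G{i:02d}", chrom, tss, tss, tss + 20_000, "other"))
        pairs = annotate_to_genes(regions, genes, window=50_000, mode=mode)
        got = set(zip(pairs["region_index"], pairs["gene"], pairs["distance"]))
        assert got == brute_annotate(regions, genes, 50_000, mode)


class TestHelpers:
    def test_genome_bins_tiles(self):
        bins = genome_bins({"chr1": 10_000}, 2000)
        assert len(bins) == 5
        assert bins.intervals[0].end == 2000

    def test_merge_regions_collapses_overlaps(self):
        a = RegionSet("a", [GenomicInterval("chr1", 0, 100),
                            GenomicInterval("chr1", 50, 150)], GENOME)
        b = RegionSet("b", [GenomicInterval("chr1", 150, 200)], GENOME)
        merged = merge_regions([a, b])
        assert [(iv.start, iv.end) for iv in merged] == [(0, 200)]
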