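"""Hypergeometric enrichment: exact tails, state/class enrichment, co-enrichment."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom as scipy_hypergeom

from synercist.enrichment import (
    CistromeCollection,
    chromhmm_enrichment,
    coenrichment_scan,
    gene_class_enrichment,
    hypergeom_upper,
    overlap_significance,
)
from synercist.intervals import GenomicInterval, RegionSet, annotate_to_genes, GeneModel

from conftest import GENOME


def enumerate_upper_tail(k, n, K, N):
    """Oracle: enumerate all C(N, n) draws, count those with >= k targets."""
    universe = range(N)
    targets = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(targets.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


class TestHypergeomUpper:
    def test_worked_example_exact(self):
        assert hypergeom_upper(3, 4, 5, 10, exact=True) == Fraction(55, 210)
        assert hypergeom_upper(3, 4, 5, 10, exact=True) == enumerate_upper_tail(3, 4, 5, 10)

    def test_tail_includes_all_mass_at_zero(self):
        assert hypergeom_upper(0, 4, 5, 10) == 1.0

    def test_degenerate_certainty(self):
        assert hypergeom_upper(5, 5, 5, 5) == 1.0

    def test_matches_scipy_sf(self):
        for N in (20, 50):
            for K, n, k in [(8, 6, 3), (25, 10, 7), (5, 5, 0)]:
                if K > N or n > N:
                    continue
                ours = hypergeom_upper(k, n, K, N)
                ref = scipy_hypergeom.sf(k - 1, N, K, n)
                assert ours == pytest.approx(ref, rel=1e-12)

    def test_monotone_in_overlap(self):
        ps = [hypergeom_upper(k, 10, 12, 40) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper(0, 4, 11, 10)


def _uniform_regions(label, n, start=0, spacing=1000, width=400, chrom="chr1"):
    return RegionSet(
        label,
        [GenomicInterval(chrom, start + i * spacing, start + i * spacing + width,
                         1.0, "none", f"{label}{i}") for i in range(n)],
        GENOME,
    )


class TestOverlapSignificance:
    def test_identical_sets_certain(self):
        u = _uniform_regions("u", 20)
        res = overlap_significance(u, u, u)
        assert res.overlap == 20 and res.p_value == 1.0

    def test_disjoint_sets_no_overlap(self):
        u = _uniform_regions("u", 40)
        a = _uniform_regions("a", 10, start=0)
        b = _uniform_regions("b", 10, start=20_000)
        res = overlap_significance(a, b, u)
        assert res.overlap == 0 and res.p_value == 1.0

    def test_empty_universe_rejected(self):
        a = _uniform_regions("a", 3)
        with pytest.raises(ValueError):
            overlap_significance(a, a, RegionSet("u", [], GENOME))


class TestChromhmmEnrichment:
    def segmentation(self, states):
        ivs = [
            GenomicInterval("chr1", i * 1000, (i + 1) * 1000, 0.0, "none", s)
            for i, s in enumerate(states)
        ]
        return RegionSet("seg", ivs, GENOME)

    def test_single_region_closed_form(self):
        # one query region inside the state: p = K/N
        seg = self.segmentation(["A"] * 3 + ["B"] * 7)
        query = RegionSet("q", [GenomicInterval("chr1", 100, 200, 1.0, "loss")], GENOME)
        table = chromhmm_enrichment({("F", "loss"): query}, seg)
        row = table[table["ChromHMM"] == "A"].iloc[0]
        assert row["p"] == pytest.approx(3 / 10)

    def test_overlapping_segmentation_rejected(self):
        seg = RegionSet("seg", [GenomicInterval("chr1", 0, 1000, 0.0, "none", "A"),
                                GenomicInterval("chr1", 500, 1500, 0.0, "none", "B")],
                        GENOME)
        q = RegionSet("q", [GenomicInterval("chr1", 0, 10, 0.0, "loss")], GENOME)
        with pytest.raises(ValueError, match="overlap"):
            chromhmm_enrichment({("F", "loss"): q}, seg)

    def test_row_completeness(self):
        seg = self.segmentation(["A", "B"] * 5)
        q1 = RegionSet("q", [GenomicInterval("chr1", 100, 200, 1.0, "loss")], GENOME)
        q2 = RegionSet("q", [GenomicInterval("chr1", 1100, 1200, 1.0, "gain")], GENOME)
        table = chromhmm_enrichment(
            {("F", "loss"): q1, ("F", "gain"): q2, ("G", "loss"): q1}, seg
        )
        assert len(table) == 2 * 3  # |states| x |(factor, direction)| pairs


class TestGeneClassEnrichment:
    def test_toy_matches_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        classes = {g: ("CoA" if i < 8 else "other") for i, g in enumerate(universe)}
        hits = ["g0", "g1", "g2", "g3", "g10"]  # 4 of 5 in the 8-gene class
        ann = _annotation_frame(hits)
        table = gene_class_enrichment(ann, classes, universe)
        row = table[table["class"] == "CoA"].iloc[0]
        assert row["p"] == pytest.approx(float(enumerate_upper_tail(4, 5, 8, 20)))

    def test_pure_class_hit_is_minimal(self):
        universe = [f"g{i}" for i in range(30)]
        classes = {g: ("CoA" if i < 6 else ("CoR" if i < 12 else "other"))
                   for i, g in enumerate(universe)}
        ann = _annotation_frame(universe[:6])  # exactly the CoA class
        table = gene_class_enrichment(ann, classes, universe).set_index("class")
        assert table.loc["CoA", "p"] == table["p"].min()
        assert table.loc["CoA", "closest_member"] == "g0"

    def test_hits_outside_universe_rejected(self):
        ann = _annotation_frame(["mystery"])
        with pytest.raises(ValueError):
            gene_class_enrichment(ann, {"g0": "CoA"}, ["g0"])


def _annotation_frame(genes):
    import pandas as pd

    return pd.DataFrame(
        {"gene": genes, "distance": range(len(genes))}
    )


class TestCoenrichmentScan:
    def build_collection(self, query, spec):
        """spec: list of (factor, n_datasets, n_query_copies_each)."""
        datasets = []
        far = 500_000
        for factor, n_sets, n_copy in spec:
            for d in range(n_sets):
                ivs = [GenomicInterval(q.chrom, q.start, q.end, 1.0, "none")
                       for q in query.intervals[:n_copy]]
                k = len(ivs)
                for j in range(10 - k):
                    s = far + (len(datasets) * 20 + j) * 1000
                    ivs.append(GenomicInterval("chr2", s, s + 400, 1.0, "none"))
                did = f"{factor}_{d:02d}"
                datasets.append((did, factor, "prostate", RegionSet(did, ivs, GENOME)))
        return CistromeCollection(datasets)

    def test_quoted_fold_change_rule(self):
        query = _uniform_regions("q", 10)
        # factor X: 4 of its 8 datasets overlap the query strongly; Y never does.
        coll = self.build_collection(query, [("X", 8, 0), ("Y", 8, 0)])
        # overwrite: make 4 X datasets query copies
        boosted = []
        for i, (did, factor, tissue, rs) in enumerate(coll.datasets):
            if factor == "X" and i < 4:
                rs = RegionSet(did, list(query.intervals), GENOME)
            boosted.append((did, factor, tissue, rs))
        coll = CistromeCollection(boosted)
        out = coenrichment_scan(query, coll, top_n=4, fc_threshold=1.2)
        x = out[out["factor"] == "X"].iloc[0]
        # observed 4/8 = 0.5, background 4/16 = 0.25 -> FC 2 > 1.2
        assert x["fold_change"] == pytest.approx(2.0)
        assert bool(x["co_enriched"])
        y = out[out["factor"] == "Y"].iloc[0]
        assert not bool(y["co_enriched"])

    def test_query_copies_rank_first_with_max_fc(self):
        query = _uniform_regions("q", 10)
        coll = self.build_collection(query, [("X", 5, 10), ("Y", 15, 0)])
        out = coenrichment_scan(query, coll, top_n=5, fc_threshold=1.2)
        x = out.iloc[0]
        assert x["factor"] == "X"
        assert x["fold_change"] == pytest.approx(len(coll) / 5)

    def test_order_invariance(self):
        query = _uniform_regions("q", 10)
        coll = self.build_collection(query, [("X", 5, 10), ("Y", 15, 0)])
        rev = CistromeCollection(list(reversed(coll.datasets)))
        a = coenrichment_scan(query, coll, top_n=5)
        b = coenrichment_scan(query, rev, top_n=5)
        assert a.equals(b)

    def test_collection_loader_round_trip(self, tmp_path):
        import pandas as pd

        from synercist.enrichment import load_collection
        from synercist.intervals import write_bed

        query = _uniform_regions("q", 5)
        coll = self.build_collection(query, [("X", 2, 0), ("Y", 2, 0)])
        bed_dir = tmp_path / "beds"
        bed_dir.mkdir()
        rows = []
        for did, factor, tissue, rs in coll.datasets:
            write_bed(rs, bed_dir / f"{did}.bed")
            rows.append({"dataset_id": did, "factor": factor, "tissue": tissue})
        manifest = tmp_path / "manifest.tsv"
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
        back = load_collection(manifest, bed_dir)
        assert [d[0] for d in back.datasets] == [d[0] for d in coll.datasets]
        assert back.factor_census == coll.factor_census
        assert len(back.datasets[0][3]) == len(coll.datasets[0][3])

    def test_tissue_filter_mean_scores(self):
        query = _uniform_regions("q", 10)
        coll = self.build_collection(query, [("X", 5, 10), ("Y", 5, 0)])
        out = coenrichment_scan(query, coll, top_n=5, tissue_filter="prostate")
        assert set(out.columns) >= {"factor", "mean_score", "n_datasets"}
        assert out.iloc[0]["factor"] == "X"
        with pytest.raises(ValueError):
            coenrichment_scan(query, coll, top_n=5, tissue_filter="liver")
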