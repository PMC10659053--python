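"""Quantification: levels, densities, editing index, annotation, motifs,
intersections."""

import numpy as np
import pandas as pd
import pytest

import editome as ed
from editome.reference import RepeatInterval
from editome.stats import intersection_sets

from conftest import make_plus_gene, make_ref


def _sites(rows):
    cols = ["chrom", "pos", "strand", "ref", "alt", "edit_type",
            "n_edited", "n_ref", "depth", "level", "p", "q", "mode"]
    out = []
    for r in rows:
        base = {"chrom": "chr1", "strand": "+", "ref": "A", "alt": "G",
                "edit_type": "A-to-G", "p": 0.0, "q": 0.0, "mode": "normal"}
        base.update(r)
        base["depth"] = base["n_edited"] + base["n_ref"]
        base["level"] = base["n_edited"] / base["depth"]
        out.append(base)
    return pd.DataFrame(out, columns=cols)


class TestLevels:
    @pytest.mark.parametrize("g,a,expected", [(5, 5, 0.5), (0, 10, 0.0), (10, 0, 1.0)])
    def test_editing_level(self, g, a, expected):
        assert ed.editing_level(g, a) == expected

    def test_zero_coverage_undefined(self):
        with pytest.raises(ValueError):
            ed.editing_level(0, 0)

    def test_overall_is_pooled_ratio(self):
        df = _sites([{"pos": 1, "n_edited": 1, "n_ref": 9}, {"pos": 2, "n_edited": 9, "n_ref": 1}])
        assert ed.overall_editing_level(df) == 0.5
        single = _sites([{"pos": 1, "n_edited": 3, "n_ref": 7}])
        assert ed.overall_editing_level(single) == pytest.approx(0.3)

    def test_overall_equals_weighted_mean_identity(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(0, n + 1))
            rows.append({"pos": i + 1, "n_edited": k, "n_ref": n - k})
        df = _sites(rows)
        overall = ed.overall_editing_level(df, min_coverage=10)
        w = df["n_edited"] + df["n_ref"]
        weighted = float((w * df["level"]).sum() / w.sum())
        assert abs(overall - weighted) < 1e-12

    def test_equal_depth_overall_is_arithmetic_mean(self):
        df = _sites([{"pos": i, "n_edited": k, "n_ref": 20 - k} for i, k in enumerate([2, 6, 10], 1)])
        assert ed.overall_editing_level(df) == pytest.approx(df["level"].mean())

    def test_coverage_floor_applied(self):
        df = _sites([{"pos": 1, "n_edited": 1, "n_ref": 3},  # depth 4 excluded
                     {"pos": 2, "n_edited": 5, "n_ref": 5}])
        assert ed.overall_editing_level(df, min_coverage=10) == 0.5

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            ed.overall_editing_level(_sites([]))


class TestDensity:
    def test_sites_per_mb(self):
        assert ed.sites_per_mb(100, 50_000_000) == 2.0
        assert ed.sites_per_mb(0, 1_000_000) == 0.0
        assert ed.sites_per_mb(100, 100_000_000) == ed.sites_per_mb(100, 50_000_000) / 2

    def test_zero_mapped_bases_undefined(self):
        with pytest.raises(ValueError):
            ed.sites_per_mb(5, 0)


class TestEditingIndex:
    def _ref_with_repeat(self, size=4000, seed=0):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=size))
        ref = make_ref(seq)
        ref.repeats.append(RepeatInterval("chr1", 500, 1500, "TE"))
        ref.te_mask["chr1"][500:1500] = True
        ref.repeat_mask["chr1"][500:1500] = True
        return ref

    def _pileup_with_te_editing(self, ref, level, depth, rng):
        arr = np.zeros((2, 4, len(ref.chroms["chr1"])), dtype=np.uint32)
        codes = ref.codes["chr1"]
        for pos in np.flatnonzero(ref.te_mask["chr1"] & (codes == 0)):
            g = rng.binomial(depth, level)
            arr[0, 2, pos] = g
            arr[0, 0, pos] = depth - g
        return ed.PileupTable(counts={"chr1": arr}, source="RNA", strands=("+", "-"))

    def test_uniform_te_editing_recovered(self):
        ref = self._ref_with_repeat()
        rng = np.random.default_rng(1)
        pile = self._pileup_with_te_editing(ref, 0.05, 100, rng)
        n_a = int((ref.te_mask["chr1"] & (ref.codes["chr1"] == 0)).sum())
        idx = ed.editing_index(pile, ref)
        se = np.sqrt(0.05 * 0.95 / (100 * n_a))
        assert abs(idx - 0.05) <= 3 * se

    def test_no_editing_gives_zero(self):
        ref = self._ref_with_repeat()
        arr = np.zeros((2, 4, 4000), dtype=np.uint32)
        codes = ref.codes["chr1"]
        for pos in np.flatnonzero(ref.te_mask["chr1"] & (codes == 0)):
            arr[0, 0, pos] = 50
        pile = ed.PileupTable(counts={"chr1": arr}, source="RNA", strands=("+", "-"))
        assert ed.editing_index(pile, ref) == 0.0

    def test_pooling_is_coverage_weighted(self):
        # two regions at indices 0.02 and 0.08 with equal A coverage pool to 0.05
        ref = self._ref_with_repeat()
        ref.repeats.append(RepeatInterval("chr1", 2000, 3000, "TE"))
        ref.te_mask["chr1"][2000:3000] = True
        arr = np.zeros((2, 4, 4000), dtype=np.uint32)
        codes = ref.codes["chr1"]
        a1 = np.flatnonzero(ref.te_mask["chr1"] & (codes == 0) & (np.arange(4000) < 1500))
        a2 = np.flatnonzero(ref.te_mask["chr1"] & (codes == 0) & (np.arange(4000) >= 2000))
        m = min(len(a1), len(a2))
        for pos in a1[:m]:
            arr[0, 2, pos] = 2
            arr[0, 0, pos] = 98
        for pos in a2[:m]:
            arr[0, 2, pos] = 8
            arr[0, 0, pos] = 92
        pile = ed.PileupTable(counts={"chr1": arr}, source="RNA", strands=("+", "-"))
        assert ed.editing_index(pile, ref) == pytest.approx(0.05)

    def test_minus_strand_positions_counted(self):
        ref = self._ref_with_repeat()
        codes = ref.codes["chr1"]
        arr = np.zeros((2, 4, 4000), dtype=np.uint32)
        t_pos = np.flatnonzero(ref.te_mask["chr1"] & (codes == 3))
        for pos in t_pos:
            arr[1, 1, pos] = 5   # genome C reads = transcript G
            arr[1, 3, pos] = 45  # genome T reads = transcript A
        pile = ed.PileupTable(counts={"chr1": arr}, source="RNA", strands=("+", "-"))
        assert ed.editing_index(pile, ref) == pytest.approx(0.1)

    def test_empty_denominator_undefined(self):
        ref = self._ref_with_repeat()
        pile = ed.PileupTable(
            counts={"chr1": np.zeros((2, 4, 4000), dtype=np.uint32)},
            source="RNA", strands=("+", "-"),
        )
        with pytest.raises(ValueError):
            ed.editing_index(pile, ref)


class TestAnnotateFeatures:
    def test_utr3_and_intergenic_assignment(self, small_ref):
        tx = next(t for t in small_ref.transcripts if t.strand == "+")
        utr3_pos = (tx.utr3[0] + tx.utr3[1]) // 2
        df = _sites([{"pos": utr3_pos + 1, "n_edited": 5, "n_ref": 5}])
        annotated, fractions = ed.annotate_features(df, small_ref)
        assert annotated.iloc[0]["feature"] == "3UTR"
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_cds_syn_nonsyn_split(self):
        #        UTR5      CDS: atg AAA CAA tga          UTR3
        seq = "TTTTTTTTTT" + "ATGAAACAATGA" + "TTTTTTTTTT"
        tx = make_plus_gene(len(seq), utr5=(0, 10), cds=((10, 22),), utr3=(22, 32))
        ref = make_ref(seq, [tx])
        # AAA codon position 2 (genome pos0 14) -> AGA nonsynonymous
        # CAA codon position 3 (genome pos0 18) -> CAG synonymous
        df = _sites([
            {"pos": 15, "n_edited": 5, "n_ref": 5},
            {"pos": 19, "n_edited": 5, "n_ref": 5},
        ])
        annotated, _ = ed.annotate_features(df, ref)
        assert list(annotated["feature"]) == ["CDS-nonsyn", "CDS-syn"]

    def test_precedence_cds_over_intron(self):
        # overlapping transcripts: position is CDS of t1 and intron of t2
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        t1 = make_plus_gene(600, utr5=(0, 30), cds=((30, 120),), utr3=(120, 150), tx_id="t1.t1")
        t2 = make_plus_gene(
            600, utr5=(0, 20), cds=((20, 50), (200, 260)), utr3=(260, 290), tx_id="t2.t1"
        )
        ref = make_ref(seq, [t1, t2])
        pos0 = next(p for p in range(60, 110) if seq[p] == "A")  # CDS(t1) & intron(t2)
        df = _sites([{"pos": pos0 + 1, "n_edited": 5, "n_ref": 5}])
        annotated, _ = ed.annotate_features(df, ref)
        assert annotated.iloc[0]["feature"].startswith("CDS")

    def test_out_of_bounds_raises(self, small_ref):
        df = _sites([{"pos": 10**7, "n_edited": 5, "n_ref": 5}])
        with pytest.raises(ValueError):
            ed.annotate_features(df, small_ref)


class TestIntersections:
    def test_two_set_example(self):
        out = intersection_sets({"A": [("c", 1, "+"), ("c", 2, "+"), ("c", 3, "+")],
                                 "B": [("c", 2, "+"), ("c", 3, "+"), ("c", 4, "+")]})
        d = {row["tissues"]: row["count"] for _, row in out.iterrows()}
        assert d == {"A,B": 2, "A": 1, "B": 1}

    def test_identical_tables_only_full_class(self):
        keys = [("c", i, "+") for i in range(5)]
        out = intersection_sets({"A": keys, "B": keys, "C": keys})
        assert len(out) == 1
        assert out.iloc[0]["tissues"] == "A,B,C" and out.iloc[0]["count"] == 5

    def test_class_counts_sum_to_union(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            sets = {
                t: {("c", int(p), "+") for p in rng.choice(300, size=rng.integers(5, 100), replace=False)}
                for t in "ABC"
            }
            out = intersection_sets(sets)
            assert out["count"].sum() == len(set().union(*sets.values()))
            # brute-force check of one exclusive class
            a_only = {k for k in sets["A"] if k not in sets["B"] and k not in sets["C"]}
            got = out[out["tissues"] == "A"]["count"]
            assert (int(got.iloc[0]) if len(got) else 0) == len(a_only)

    def test_requires_two_tissues(self):
        with pytest.raises(ValueError):
            intersection_sets({"A": []})


class TestMotifMatrix:
    def test_center_position_is_all_A(self, small_ref):
        scen = ed.random_scenario(small_ref, n_sites=200, n_snps=0, n_hyper_clusters=0, seed=9)
        truth = ed.plant_truth(small_ref, scen)
        df = truth.edits.rename(columns={})
        mat = ed.motif_matrix(df, small_ref)
        assert mat.loc[0, "A"] == pytest.approx(1.0)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_minus_strand_neighbors_complemented(self):
        seq = "GGCAGG"  # genome; '-' site at T? construct explicitly below
        # '-' strand site at pos0=3 needs genome T there: build sequence GCTTAG
        seq = "GCTTAG"
        ref = make_ref(seq)
        # transcript-strand: site A at genome T (pos0 2); upstream = comp(seq[3]) = A, downstream = comp(seq[1]) = G
        df = _sites([{"pos": 3, "strand": "-", "n_edited": 5, "n_ref": 5}])
        mat = ed.motif_matrix(df, ref)
        assert mat.loc[-1, "A"] == 1.0
        assert mat.loc[1, "G"] == 1.0

    def test_planted_upstream_bias_recovered(self, small_ref):
        scen = ed.random_scenario(
            small_ref, n_sites=800, n_snps=0, n_hyper_clusters=0, upstream_A_bias=0.9, seed=10
        )
        truth = ed.plant_truth(small_ref, scen)
        mat = ed.motif_matrix(truth.edits, small_ref)
        assert abs(mat.loc[-1, "A"] - 0.9) <= 0.05
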