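"""Scenario planting and read simulation against simple stochastic oracles."""

import numpy as np
import pysam
import pytest

import editome as ed
from editome.simulate import PlannedEdit, PlannedSNP

from conftest import make_plus_gene, make_ref


def _scenario(sites=(), snps=(), clusters=(), conditions=("T27", "T13"), tissues=("brain",)):
    return ed.EditScenario(
        sites=list(sites),
        snps=list(snps),
        hyper_clusters=list(clusters),
        conditions=conditions,
        tissues=tissues,
    )


def _edit(chrom, pos, strand, level=0.5, conditions=("T27", "T13")):
    return PlannedEdit(
        chrom=chrom, pos=pos, strand=strand,
        levels={c: level for c in conditions}, tissues=("brain",),
    )


class TestPlantTruth:
    def test_edit_at_non_A_rejected(self):
        ref = make_ref("CCCCCCCCCC")
        with pytest.raises(ed.PlacementError):
            ed.plant_truth(ref, _scenario(sites=[_edit("chr1", 4, "+")]))

    def test_minus_strand_edit_records_genome_T(self):
        seq = "GGGGTGGGGG"  # genome T at pos 4 is transcript A on '-'
        ref = make_ref(seq)
        truth = ed.plant_truth(ref, _scenario(sites=[_edit("chr1", 4, "-")]))
        row = truth.edits.iloc[0]
        assert row["genome_ref"] == "T"
        assert row["strand"] == "-"
        # and a '+' edit at the same T must be rejected
        with pytest.raises(ed.PlacementError):
            ed.plant_truth(ref, _scenario(sites=[_edit("chr1", 4, "+")]))

    def test_collision_error_and_drop_accounting(self):
        ref = make_ref("AAAAAAAAAA")
        sites = [_edit("chr1", 3, "+")]
        snps = [PlannedSNP(chrom="chr1", pos=3, alt="C", genotype="het")]
        with pytest.raises(ed.CollisionError):
            ed.plant_truth(ref, _scenario(sites=sites, snps=snps))
        truth = ed.plant_truth(ref, _scenario(sites=sites, snps=snps), on_collision="drop")
        assert len(truth.edits) == 0
        assert truth.n_rejected_collisions == 1

    def test_conservation_of_requested_sites(self, small_ref):
        scen = ed.random_scenario(small_ref, n_sites=300, n_snps=20, n_hyper_clusters=0, seed=11)
        truth = ed.plant_truth(small_ref, scen)
        assert len(truth.edits) == len(scen.sites) - truth.n_rejected_collisions
        # planted edits are transcript-strand adenosines by construction
        for _, r in truth.edits.iterrows():
            expected = "A" if r["strand"] == "+" else "T"
            assert r["genome_ref"] == expected


class TestReadSimulation:
    def test_determinism_byte_identical(self, small_ref, tmp_path):
        scen = ed.random_scenario(small_ref, n_sites=50, n_snps=5, n_hyper_clusters=1, seed=3)
        truth = ed.plant_truth(small_ref, scen)
        params = ed.ReadSimParams(coverage_rna=10, coverage_dna=5, seed=3)
        a = ed.simulate_rna_reads(small_ref, truth, params, "T27", 1, "brain", tmp_path / "a")
        b = ed.simulate_rna_reads(small_ref, truth, params, "T27", 1, "brain", tmp_path / "b")
        assert open(a.rna_sam, "rb").read() == open(b.rna_sam, "rb").read()
        assert open(a.unmapped_sam, "rb").read() == open(b.unmapped_sam, "rb").read()
        c = ed.simulate_rna_reads(small_ref, truth, params, "T27", 2, "brain", tmp_path / "c")
        assert open(a.rna_sam, "rb").read() != open(c.rna_sam, "rb").read()

    def test_edited_read_counts_follow_binomial(self, tmp_path):
        # single '+' gene, one site at level 0.3, error-free: the edited-read
        # count at the site is Binomial(coverage, 0.3); across 40 libraries
        # the pooled level must sit within 3 SE of the truth
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=2000))
        tx = make_plus_gene(2000, utr5=(100, 400), cds=((400, 1300),), utr3=(1300, 1900))
        ref = make_ref(seq, [tx])
        pos = seq.index("A", 800)
        true_level = 0.3
        site = PlannedEdit("chr1", pos, "+", {"T27": true_level}, ("brain",))
        scen = _scenario(sites=[site], conditions=("T27",))
        truth = ed.plant_truth(ref, scen)
        g = n = 0
        for i in range(40):
            params = ed.ReadSimParams(coverage_rna=30, base_error_rate=0.0, seed=100 + i)
            lib = ed.simulate_rna_reads(ref, truth, params, "T27", 1, "brain", tmp_path / str(i))
            with pysam.AlignmentFile(lib.rna_sam, "r") as fh:
                for read in fh.fetch(until_eof=True):
                    s, e = read.reference_start, read.reference_end
                    if s <= pos < e:
                        n += 1
                        if read.query_sequence[pos - s] == "G":
                            g += 1
        se = np.sqrt(true_level * (1 - true_level) / n)
        assert abs(g / n - true_level) <= 3 * se

    def test_het_snp_allele_fraction_in_dna(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        ref = make_ref(seq)
        snp = PlannedSNP("chr1", 1500, alt="G" if seq[1500] != "G" else "C", genotype="het")
        truth = ed.plant_truth(ref, _scenario(snps=[snp]))
        params = ed.ReadSimParams(coverage_dna=200, base_error_rate=0.0, seed=5)
        lib = ed.simulate_dna_reads(ref, truth, params, tmp_path)
        alt = n = 0
        with pysam.AlignmentFile(lib.dna_sam, "r") as fh:
            for read in fh.fetch(until_eof=True):
                s = read.reference_start
                if s <= 1500 < s + 150:
                    n += 1
                    if read.query_sequence[1500 - s] == snp.alt:
                        alt += 1
        assert n > 100
        assert abs(alt / n - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_no_noise_null_has_no_mismatches(self, tmp_path):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        tx = make_plus_gene(2000, utr5=(100, 400), cds=((400, 1300),), utr3=(1300, 1900))
        ref = make_ref(seq, [tx])
        pos = seq.index("A", 500)
        site = PlannedEdit("chr1", pos, "+", {"T27": 0.0}, ("brain",))
        truth = ed.plant_truth(ref, _scenario(sites=[site], conditions=("T27",)))
        params = ed.ReadSimParams(coverage_rna=20, base_error_rate=0.0, seed=9)
        lib = ed.simulate_rna_reads(ref, truth, params, "T27", 1, "brain", tmp_path)
        with pysam.AlignmentFile(lib.rna_sam, "r") as fh:
            for read in fh.fetch(until_eof=True):
                s = read.reference_start
                assert read.query_sequence == seq[s : s + 150]

    def test_strand_protocol_recovers_transcript_strand(self, small_ref, tmp_path):
        scen = ed.random_scenario(small_ref, n_sites=40, n_snps=0, n_hyper_clusters=0, seed=4)
        truth = ed.plant_truth(small_ref, scen)
        params = ed.ReadSimParams(coverage_rna=5, base_error_rate=0.0, seed=4)
        lib = ed.simulate_rna_reads(small_ref, truth, params, "T27", 1, "brain", tmp_path)
        gene_by_span = [(t.start, t.end, t.strand) for t in small_ref.transcripts]
        checked = 0
        with pysam.AlignmentFile(lib.rna_sam, "r") as fh:
            for read in fh.fetch(until_eof=True):
                for s, e, strand in gene_by_span:
                    if s <= read.reference_start and read.reference_end <= e:
                        assert ("-" if read.is_reverse else "+") == strand
                        checked += 1
                        break
        assert checked > 50

    def test_error_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            ed.ReadSimParams(base_error_rate=0.2)
        with pytest.raises(ValueError):
            ed.ReadSimParams(coverage_rna=0)


def test_motif_bias_is_planted(small_ref):
    scen = ed.random_scenario(
        small_ref, n_sites=600, n_snps=0, n_hyper_clusters=0,
        upstream_A_bias=0.9, seed=6,
    )
    truth = ed.plant_truth(small_ref, scen)
    frac = (truth.edits["upstream"] == "A").mean()
    assert abs(frac - 0.9) <= 0.05
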