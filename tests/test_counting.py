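import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riboload.annotation import TranscriptModel
from riboload.counting import (
    compute_rpkm,
    count_reads,
    read_alignment_sam,
    read_alignment_tsv,
    read_length_histogram,
    region_density,
    replicate_correlation,
    rpkm_table,
    write_alignment_tsv,
)
from riboload.simulate import write_sam


class TestCountReads:
    def test_one_read_per_region(self, single_exon_model, toy_reads):
        cm = count_reads(toy_reads, {"T1": single_exon_model})
        c = cm.counts[("RPF", "s1")]
        assert c[("G1", "utr5")] == 1
        assert c[("G1", "cds")] == 1
        assert c[("G1", "utr3")] == 1
        assert c[("G1", "gene_total")] == 3
        assert cm.library_size[("RPF", "s1")] == 3

    def test_empty_reads_all_zero(self, single_exon_model):
        empty = pd.DataFrame(
            columns=["sample", "assay", "transcript", "start", "length"]
        )
        cm = count_reads(empty, {"T1": single_exon_model})
        assert cm.counts.empty or (cm.counts.to_numpy() == 0).all()
        assert cm.library_size.sum() == 0

    def test_uniform_reads_tally_exactly(self, single_exon_model, rng):
        """1000 uniformly placed reads are all recovered (direct tally oracle)."""
        n = 1000
        starts = rng.integers(1, 972, size=n)  # stay on the transcript
        reads = pd.DataFrame(
            {
                "sample": "s1", "assay": "mRNA", "transcript": "T1",
                "start": starts, "length": 30,
            }
        )
        cm = count_reads(reads, {"T1": single_exon_model})
        assert cm.counts[("mRNA", "s1")][("G1", "gene_total")] == n
        # oracle: direct tally by containment of the 5'-end base
        exp_utr5 = int((starts <= 100).sum())
        exp_cds = int(((starts > 100) & (starts <= 700)).sum())
        assert cm.counts[("mRNA", "s1")][("G1", "utr5")] == exp_utr5
        assert cm.counts[("mRNA", "s1")][("G1", "cds")] == exp_cds

    def test_off_transcript_read_rejected_and_logged(self, single_exon_model):
        reads = pd.DataFrame(
            {
                "sample": ["s1", "s1"], "assay": ["RPF", "RPF"],
                "transcript": ["T1", "T1"], "start": [990, 100],
                "length": [30, 30],
            }
        )
        cm = count_reads(reads, {"T1": single_exon_model})
        assert cm.library_size[("RPF", "s1")] == 1
        assert cm.rejected[("RPF", "s1")] == 1

    def test_boundary_read_assigned_by_five_prime_end(self, single_exon_model):
        # 5' end on the last UTR5 base; read body spans into the CDS
        reads = pd.DataFrame(
            {
                "sample": ["s1"], "assay": ["RPF"], "transcript": ["T1"],
                "start": [100], "length": [30],
            }
        )
        cm = count_reads(reads, {"T1": single_exon_model})
        assert cm.counts[("RPF", "s1")][("G1", "utr5")] == 1
        assert cm.counts[("RPF", "s1")][("G1", "cds")] == 0

    def test_library_size_conserves_gene_totals(self, single_exon_model, rng):
        reads = pd.DataFrame(
            {
                "sample": rng.choice(["s1", "s2"], 500),
                "assay": "RPF",
                "transcript": "T1",
                "start": rng.integers(1, 900, 500),
                "length": 30,
            }
        )
        cm = count_reads(reads, {"T1": single_exon_model})
        totals = cm.counts.xs("gene_total", level="region").sum(axis=0)
        assert (totals == cm.library_size).all()


class TestRpkm:
    def test_closed_form(self):
        assert compute_rpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert compute_rpkm(0, 1000, 10**6) == 0.0

    def test_hand_computed_example(self):
        # 37 reads, 2460-nt feature, 8,412,301 mapped:
        # 37 / 2.460 / 8.412301 = 1.78795... (direct arithmetic oracle)
        expected = 37 / (2460 / 1e3) / (8_412_301 / 1e6)
        assert compute_rpkm(37, 2460, 8_412_301) == pytest.approx(expected, rel=1e-12)

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="empty library"):
            compute_rpkm(5, 1000, 0)
        with pytest.raises(ValueError):
            compute_rpkm(5, 0, 10**6)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        k=st.integers(0, 10**6),
        L=st.integers(1, 10**5),
        N=st.integers(1, 10**8),
        c=st.integers(2, 50),
    )
    def test_scaling_invariances(self, k, L, N, c):
        """RPKM is linear in counts, inverse in length and depth, and
        invariant to scaling counts and library size together."""
        base = compute_rpkm(k, L, N)
        assert compute_rpkm(c * k, L, N) == pytest.approx(c * base, rel=1e-9)
        assert compute_rpkm(k, c * L, N) == pytest.approx(base / c, rel=1e-9)
        assert compute_rpkm(k, L, c * N) == pytest.approx(base / c, rel=1e-9)
        assert compute_rpkm(c * k, L, c * N) == pytest.approx(base, rel=1e-9)

    def test_region_density_matches_rpkm_at_default_scale(self):
        assert region_density(50, 200, 10**6) == pytest.approx(
            compute_rpkm(50, 200, 10**6)
        )
        with pytest.raises(ValueError, match="zero-length"):
            region_density(5, 0, 1000)

    def test_rpkm_table_uses_transcript_length(self, single_exon_model, toy_reads):
        cm = count_reads(toy_reads, {"T1": single_exon_model})
        table = rpkm_table(cm, {"T1": single_exon_model})
        # 3 reads on a 1000-nt transcript in a 3-read library
        assert table.loc["G1", ("RPF", "s1")] == pytest.approx(
            compute_rpkm(3, 1000, 3)
        )


class TestQc:
    def test_read_length_histogram(self):
        reads = pd.DataFrame(
            {"sample": "s", "assay": "RPF", "transcript": "T",
             "start": 1, "length": [28, 28, 30, 31]}
        )
        h = read_length_histogram(reads)
        assert h[28] == 2 and h[30] == 1 and h[31] == 1

    def test_correlation_of_identical_vectors_is_one(self, rng):
        x = rng.lognormal(2, 1, 50)
        assert replicate_correlation(x, x) == pytest.approx(1.0)

    def test_anticorrelated_log_vectors(self):
        # construct y so that log2(y+pc) = -log2(x+pc) + c exactly
        lx = np.linspace(1.0, 5.0, 20)
        x = 2.0**lx - 1e-2
        y = 2.0 ** (6.0 - lx) - 1e-2
        assert replicate_correlation(x, y) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        """10-element vectors against the covariance-ratio definition."""
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        y = np.array([2, 1, 4, 3, 6, 5, 8, 7, 10, 9], dtype=float)
        lx, ly = np.log2(x + 1e-2), np.log2(y + 1e-2)
        num = ((lx - lx.mean()) * (ly - ly.mean())).sum()
        den = np.sqrt(((lx - lx.mean()) ** 2).sum() * ((ly - ly.mean()) ** 2).sum())
        assert replicate_correlation(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation([1.0, 2.0], [1.0, 2.0])


class TestIo:
    def test_tsv_round_trip(self, toy_reads, tmp_path):
        p = str(tmp_path / "reads.tsv")
        write_alignment_tsv(toy_reads, p)
        back = read_alignment_tsv(p)
        assert len(back) == len(toy_reads)
        assert list(back["start"]) == list(toy_reads["start"])

    def test_tsv_rejects_bad_coordinates(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample\tassay\ttranscript\tstart\tlength\ns\tRPF\tT\t0\t30\n")
        with pytest.raises(ValueError, match="non-positive"):
            read_alignment_tsv(str(p))

    def test_transcript_sam_round_trip(self, single_exon_model, toy_reads, tmp_path):
        p = str(tmp_path / "reads.sam")
        write_sam(toy_reads, [single_exon_model], p, genomic=False)
        back = read_alignment_sam(p, "s1", "RPF")
        assert sorted(back["start"]) == sorted(toy_reads["start"])
        assert set(back["transcript"]) == {"T1"}

    def test_genomic_sam_projects_back_to_transcript(
        self, two_exon_minus_model, tmp_path
    ):
        """Writing genomic SAM through exon blocks and reading it back
        recovers the transcript-space 5' ends, including a splice-spanning
        minus-strand read."""
        reads = pd.DataFrame(
            {
                "sample": "s1", "assay": "RPF", "transcript": "T2",
                "start": [1, 390, 550], "length": [28, 28, 28],
            }
        )
        p = str(tmp_path / "g.sam")
        write_sam(reads, [two_exon_minus_model], p, genomic=True)
        models = {"T2": two_exon_minus_model}
        back = read_alignment_sam(p, "s1", "RPF", models=models)
        assert sorted(back["start"]) == [1, 390, 550]
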