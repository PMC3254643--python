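"""Directed alignment, ploidy-aware consensus calling, SNP rates."""

import numpy as np
import pytest

from snptree.consensus import ConsensusReference
from snptree.pairwise import (
    align_reads,
    all_pairs,
    build_pair_pileup,
    call_site_consensus,
    count_directed_snps,
    snps_from_pileup,
)
from snptree.seqio import Read, revcomp
from snptree.simulate import jc_p_distance

from conftest import make_reads, random_sequence, tile_reads


@pytest.fixture
def reference(rng):
    return ConsensusReference("B", [("r00000", random_sequence(rng, 500))])


class TestAlignReads:
    def test_exact_substring(self, reference):
        seq = reference.sequences[0][1]
        read = Read("q0", seq[100:140], "A")
        alns = align_reads([read], reference)
        assert len(alns) == 1
        assert alns[0].ref_offset == 100 and alns[0].mismatch_count == 0

    def test_minus_strand(self, reference):
        seq = reference.sequences[0][1]
        read = Read("q0", revcomp(seq[200:240]), "A")
        (aln,) = align_reads([read], reference)
        assert aln.ref_offset == 200 and aln.strand == "-"
        assert aln.sequence == seq[200:240]

    def test_one_mismatch_outside_seed(self, reference):
        seq = reference.sequences[0][1]
        bases = list(seq[100:140])
        bases[30] = "A" if bases[30] != "A" else "C"
        (aln,) = align_reads([Read("q0", "".join(bases), "A")], reference,
                             max_mismatches=2)
        assert aln.mismatch_count == 1

    def test_simulated_reads_fully_aligned(self, rng, reference):
        seq = reference.sequences[0][1]
        reads = []
        for i in range(1000):
            start = int(rng.integers(0, len(seq) - 39))
            s = seq[start : start + 40]
            if rng.random() < 0.5:
                s = revcomp(s)
            reads.append(Read(f"q{i}", s, "A"))
        alns = align_reads(reads, reference)
        assert len(alns) == 1000
        assert sum(len(a) for a in alns) == sum(len(r.sequence) for r in reads)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_reads([], ConsensusReference("B", []))


class TestCallSiteConsensus:
    @pytest.mark.parametrize(
        "counts,ploidy,expected",
        [
            ({"A": 5}, 1, "A"),            # clear call
            ({"A": 2}, 1, None),           # below min_depth
            ({"A": 4, "G": 2}, 3, "A"),    # one homoeolog cannot flip consensus
        ],
    )
    def test_rule(self, counts, ploidy, expected):
        assert call_site_consensus(counts, ploidy) == expected

    def test_min_allele_fraction_gate(self):
        # majority rule for haploids: 3/6 is not >= 1/2 - only exactly 1/2
        assert call_site_consensus({"A": 3, "G": 3}, 1) == "A"  # tie at the bound
        assert call_site_consensus({"A": 2, "G": 3, "C": 3}, 1) is None

    def test_invalid_ploidy(self):
        with pytest.raises(ValueError):
            call_site_consensus({"A": 3}, 0)


class TestCountDirectedSnps:
    def _tiling_alignments(self, ref_seq, query_seq, copies=5):
        """Align *copies* exact tilings of query_seq against the reference."""
        ref = ConsensusReference("B", [("r00000", ref_seq)])
        reads = []
        for c in range(copies):
            reads += [
                Read(f"q{c}_{i}", query_seq[i : i + 40], "A")
                for i in range(0, len(query_seq) - 39, 40)
            ]
        return align_reads(reads, ref, max_mismatches=3), ref

    def test_rate_arithmetic(self, rng):
        """25 aligned reads of 40 bp with 2 consensus/reference differences
        give exactly 2/1000 SNPs per aligned base."""
        ref_seq = random_sequence(rng, 200)
        query = list(ref_seq)
        for pos in (30, 150):  # outside every tiling read's first-20 seed
            query[pos] = "A" if ref_seq[pos] != "A" else "C"
        alns, ref = self._tiling_alignments(ref_seq, "".join(query), copies=5)
        assert len(alns) == 25
        result = count_directed_snps(alns, ref, ploidy=1, query_sample="A")
        assert result.aligned_bases == 1000
        assert result.snp_count == 2
        assert result.snp_rate == pytest.approx(0.002)

    def test_self_comparison_is_zero(self, rng):
        ref_seq = random_sequence(rng, 200)
        alns, ref = self._tiling_alignments(ref_seq, ref_seq, copies=5)
        result = count_directed_snps(alns, ref, ploidy=3, query_sample="B")
        assert result.snp_count == 0 and result.snp_rate == 0.0

    def test_no_alignments_is_an_error(self, rng):
        ref = ConsensusReference("B", [("r00000", random_sequence(rng, 100))])
        with pytest.raises(ValueError, match="no alignable reads"):
            count_directed_snps([], ref, ploidy=1, query_sample="A")

    def test_duplicating_reads_halves_rate(self, rng):
        """SNPs are counted per site, so doubling read depth doubles the
        denominator but not the count: the rate halves.  (This is the
        deliberate weighting toward low-coverage samples.)"""
        ref_seq = random_sequence(rng, 200)
        query = list(ref_seq)
        query[100] = "A" if ref_seq[100] != "A" else "C"
        alns, ref = self._tiling_alignments(ref_seq, "".join(query), copies=5)
        single = count_directed_snps(alns, ref, ploidy=1, query_sample="A")
        doubled = count_directed_snps(alns + alns, ref, ploidy=1, query_sample="A")
        assert doubled.snp_count == single.snp_count
        assert doubled.aligned_bases == 2 * single.aligned_bases
        assert doubled.snp_rate == pytest.approx(single.snp_rate / 2)

    def test_scalar_and_vector_consensus_agree(self, rng):
        """The per-site scalar rule and the vectorised pile-up rule call
        the same consensus on the same counts."""
        ref_seq = random_sequence(rng, 120)
        reads = []
        for c in range(6):
            q = list(ref_seq)
            if c < 4:  # 4-of-6 alternate allele at one site
                q[60] = "A" if ref_seq[60] != "A" else "C"
            reads += [Read(f"q{c}_{i}", "".join(q[i : i + 40]), "A")
                      for i in range(0, 81, 40)]
        ref = ConsensusReference("B", [("r00000", ref_seq)])
        alns = align_reads(reads, ref, max_mismatches=2)
        pileup = build_pair_pileup(alns, ref)
        for ploidy in (1, 3):
            snps, _ = snps_from_pileup(pileup, ploidy)
            counts = {"A": 0, "C": 0, "G": 0, "T": 0}
            for aln in alns:
                lo, hi = aln.ref_offset, aln.ref_offset + len(aln)
                if lo <= 60 < hi:
                    counts[aln.sequence[60 - lo]] += 1
            scalar = call_site_consensus(counts, ploidy)
            assert (snps == 1) == (scalar is not None and scalar != ref_seq[60])

    def test_rate_matches_direct_site_count_oracle(self, rng):
        """At 1x tiling coverage with error-free reads, every SNP the
        caller reports is a realized haplotype difference inside an
        aligned read, and vice versa: the rate equals the direct
        haplotype-vs-haplotype mismatch count over aligned bases."""
        n_sites = 20_000
        d = 0.005
        seq_b = random_sequence(rng, n_sites)
        arr = np.frombuffer(seq_b.encode(), dtype=np.uint8).copy()
        hit = rng.random(n_sites) < jc_p_distance(d)
        lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
        seq_a = "".join(
            lut[arr[i]][int(rng.integers(3))] if hit[i] else chr(arr[i])
            for i in range(n_sites)
        )
        ref = ConsensusReference("B", [("r00000", seq_b)])
        reads = make_reads(
            [seq_a[i : i + 40] for i in range(0, n_sites - 39, 40)], sample="A"
        )
        alns = align_reads(reads, ref, max_mismatches=5)
        assert alns, "tiling reads must align"
        result = count_directed_snps(alns, ref, ploidy=1, query_sample="A",
                                     min_depth=1)
        # independent oracle: direct string comparison over aligned windows
        oracle = 0
        for aln in alns:
            window = seq_b[aln.ref_offset : aln.ref_offset + len(aln)]
            oracle += sum(a != b for a, b in zip(aln.sequence, window))
        assert result.snp_count == oracle
        assert result.snp_rate == pytest.approx(oracle / result.aligned_bases)


class TestAllPairs:
    def _identical_panel(self, rng, n_samples):
        src = random_sequence(rng, 300)
        read_sets, references = {}, {}
        for i in range(n_samples):
            s = f"s{i}"
            reads = []
            for _ in range(3):
                reads += tile_reads(src, step=10, sample=s)
            read_sets[s] = reads
            references[s] = ConsensusReference(s, [("r00000", src)])
        return read_sets, references

    def test_two_samples_two_results(self, rng):
        read_sets, references = self._identical_panel(rng, 2)
        results = all_pairs(read_sets, references, ploidy=1)
        assert len(results) == 2

    def test_identical_samples_rate_zero(self, rng):
        read_sets, references = self._identical_panel(rng, 3)
        results = all_pairs(read_sets, references, ploidy=3)
        assert len(results) == 6
        assert all(r.snp_rate == 0.0 for r in results)

    def test_single_sample_rejected(self, rng):
        read_sets, references = self._identical_panel(rng, 1)
        with pytest.raises(ValueError):
            all_pairs(read_sets, references)
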