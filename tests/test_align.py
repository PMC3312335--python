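"""Aligner correctness against a brute-force all-placements oracle."""

import numpy as np
import pytest

from oracles import brute_force_align, rc

from alevar.align import (
    AlignStatus,
    align_iterative,
    align_read,
    build_reference,
    write_sam,
)
from alevar.synth import Contig, Read, ReadSet, simulate_reads


def _contig(cid, seq, cls="chromosome"):
    return Contig(cid, seq, cls)


class TestBuildReference:
    def test_concatenation_and_offsets(self):
        ref = build_reference([_contig("c1", "ACGT"), _contig("c2", "TTTT")])
        assert ref.sequence == "ACGTTTTT"
        assert ref.offsets == {"c1": 0, "c2": 4}
        assert ref.lengths == {"c1": 4, "c2": 4}

    def test_coordinate_maps_are_inverse(self):
        ref = build_reference([_contig("c1", "ACGT"), _contig("c2", "TTTTTT")])
        assert ref.to_local(5) == ("c2", 2)
        for g in range(ref.total_length):
            cid, local = ref.to_local(g)
            assert ref.to_global(cid, local) == g

    def test_many_contigs_total_length(self):
        rng = np.random.default_rng(0)
        contigs = [
            _contig(f"c{i}", "".join(rng.choice(list("ACGT"), size=30)))
            for i in range(279)
        ]
        ref = build_reference(contigs)
        assert ref.total_length == sum(len(c) for c in contigs)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_reference([_contig("c1", "ACGT"), _contig("c1", "TTTT")])


class TestAlignReadTinyExamples:
    """Hand-sized cases; every expectation below was computed with the
    brute-force scan in oracles.py before being frozen here."""

    def test_repeat_yields_ambiguous(self):
        ref = build_reference([_contig("c1", "ACGTACGTAC")])
        status, rec = align_read(Read("r", "ACGT"), ref, max_mm=0, k=2)
        assert status is AlignStatus.AMBIGUOUS and rec is None

    def test_cross_strand_tie_is_ambiguous(self):
        # revcomp("ACGA") = "TCGT" also matches window 1 of "ACGTTGCA"
        # at distance 1, so the two strands tie at the same position
        ref = build_reference([_contig("c1", "ACGTTGCA")])
        assert brute_force_align("ACGA", [("c1", "ACGTTGCA")], 1)[0] == "ambiguous"
        status, _ = align_read(Read("r", "ACGA"), ref, max_mm=1, k=2)
        assert status is AlignStatus.AMBIGUOUS

    def test_unique_one_mismatch_placement(self):
        seq = "ACGGTGCATTCCAGGA"
        status_o, best_o, hits_o = brute_force_align("TGCATACC", [("c1", seq)], 1)
        assert (status_o, best_o, hits_o) == ("aligned", 1, [("c1", 5, "+")])
        ref = build_reference([_contig("c1", seq)])
        status, rec = align_read(Read("r", "TGCATACC"), ref, max_mm=1, k=2)
        assert status is AlignStatus.ALIGNED
        assert (rec.contig_id, rec.position, rec.strand, rec.mismatch_count) == ("c1", 5, "+", 1)

    def test_reverse_complement_placement(self):
        seq = "AACCGGTTACGTGCAA"
        read = rc(seq[2:10])
        ref = build_reference([_contig("c1", seq)])
        status, rec = align_read(Read("r", read), ref, max_mm=0, k=2)
        assert status is AlignStatus.ALIGNED
        assert (rec.position, rec.strand, rec.mismatch_count) == (3, "-", 0)

    def test_unaligned_when_nothing_fits(self):
        ref = build_reference([_contig("c1", "AAAAAAAAAAAA")])
        status, _ = align_read(Read("r", "GGGGGG"), ref, max_mm=1, k=2)
        assert status is AlignStatus.UNALIGNED

    def test_junction_spanning_placement_rejected(self):
        # the read matches only across the c1|c2 junction of the
        # concatenation, which is not a real genomic locus
        ref = build_reference([_contig("c1", "AAAACCCC"), _contig("c2", "GGGGTTTT")])
        status, _ = align_read(Read("r", "CCCCGGGG"), ref, max_mm=0, k=2)
        assert status is AlignStatus.UNALIGNED

    def test_n_bases_count_as_mismatches(self):
        assert brute_force_align("AANC", [("c1", "AACCTTGG")], 1) == (
            "aligned", 1, [("c1", 1, "+")],
        )
        ref = build_reference([_contig("c1", "AACCTTGG")])
        status, rec = align_read(Read("r", "AANC"), ref, max_mm=1, k=2)
        assert status is AlignStatus.ALIGNED
        assert (rec.position, rec.mismatch_count) == (1, 1)
        status, _ = align_read(Read("r", "AANC"), ref, max_mm=0, k=2)
        assert status is AlignStatus.UNALIGNED


@pytest.mark.parametrize(
    "read_len,max_mm",
    [(30, 2), (36, 1), (80, 5)],  # exercises both exhaustive and seeded paths
)
def test_oracle_equivalence_random_genome(read_len, max_mm):
    """align_read == brute-force Hamming scan on small two-contig genomes."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    c1 = "".join(rng.choice(bases, size=3000))
    c2 = "".join(rng.choice(bases, size=1500))
    contigs = [("g1", c1), ("g2", c2)]
    ref = build_reference([_contig("g1", c1), _contig("g2", c2, "plasmid")])
    seqs = {"g1": c1, "g2": c2}

    reads = []
    for i in range(120):
        cid = "g1" if rng.random() < 0.7 else "g2"
        start = int(rng.integers(0, len(seqs[cid]) - read_len + 1))
        seq = list(seqs[cid][start : start + read_len])
        for _ in range(int(rng.integers(0, max_mm + 3))):  # some exceed the budget
            j = int(rng.integers(read_len))
            seq[j] = str(rng.choice(bases[bases != seq[j]]))
        s = "".join(seq)
        if rng.random() < 0.5:
            s = rc(s)
        reads.append(s)
    reads.append("".join(rng.choice(bases, size=read_len)))  # random junk

    for i, seq in enumerate(reads):
        status_o, best_o, hits_o = brute_force_align(seq, contigs, max_mm)
        status, rec = align_read(Read(f"r{i}", seq), ref, max_mm=max_mm)
        assert status.value == status_o, f"read {i}"
        if status is AlignStatus.ALIGNED:
            assert (rec.contig_id, rec.position, rec.strand) == hits_o[0]
            assert rec.mismatch_count == best_o


class TestAlignIterative:
    def test_planted_distances_map_to_levels(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        chrom = "".join(rng.choice(bases, size=4000))
        ref = build_reference([_contig("c1", chrom)])

        def mutate(seq, n):
            seq = list(seq)
            for j in rng.choice(len(seq), size=n, replace=False):
                seq[j] = str(rng.choice(bases[bases != seq[j]]))
            return "".join(seq)

        reads = ReadSet(
            reads=(
                Read("exact", chrom[100:180]),
                Read("two_mm", mutate(chrom[900:980], 2)),
                Read("six_mm", mutate(chrom[2000:2080], 6)),
            ),
            read_len=80,
        )
        result = align_iterative(reads, ref, max_level=5)
        levels = {r.read_id: r.iteration_level for r in result.alignments}
        assert levels == {"exact": 0, "two_mm": 2}
        assert [r.id for r in result.leftovers] == ["six_mm"]

    def test_error_free_simulation_all_level_zero(self, small_genome):
        reads = simulate_reads(small_genome, depth=3, read_len=80, err_rate=0.0, seed=5)
        ref = build_reference(small_genome.contigs)
        result = align_iterative(reads, ref, max_level=5)
        assert len(result.alignments) + len(result.ambiguous) == len(reads)
        assert all(r.iteration_level == 0 for r in result.alignments)

    def test_iteration_level_equals_mismatch_count(self, small_genome):
        reads = simulate_reads(small_genome, depth=3, read_len=80, err_rate=0.02, seed=6)
        ref = build_reference(small_genome.contigs)
        result = align_iterative(reads, ref, max_level=5)
        assert result.alignments  # sanity
        for rec in result.alignments:
            assert rec.iteration_level == rec.mismatch_count
            # placement lands fully inside its contig
            assert rec.position + len(rec.sequence) - 1 <= ref.lengths[rec.contig_id]

    def test_aligned_count_monotone_in_level_cap(self, small_genome):
        reads = simulate_reads(small_genome, depth=2, read_len=80, err_rate=0.03, seed=8)
        ref = build_reference(small_genome.contigs)
        counts = [
            len(align_iterative(reads, ref, max_level=lvl).alignments)
            for lvl in range(6)
        ]
        assert counts == sorted(counts)

    def test_empty_read_set(self, small_genome):
        ref = build_reference(small_genome.contigs)
        result = align_iterative([], ref)
        assert result.alignments == () and result.leftovers == ()


def test_sam_output_parses_with_pysam(small_genome, tmp_path):
    pysam = pytest.importorskip("pysam")
    reads = simulate_reads(small_genome, depth=2, read_len=60, err_rate=0.01, seed=9)
    ref = build_reference(small_genome.contigs)
    result = align_iterative(reads, ref, max_level=5)
    path = tmp_path / "aln.sam"
    write_sam(result, ref, path)
    with pysam.AlignmentFile(str(path), "r") as sam:
        assert list(sam.references) == ["chr", "pSMALL"]
        n_mapped = n_unmapped = 0
        for rec in sam:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            n_mapped += 1
            assert rec.cigarstring == "60M"
            assert rec.get_tag("NM") == rec.get_tag("XI")
    assert n_mapped == len(result.alignments)
    assert n_unmapped == len(result.leftovers)
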