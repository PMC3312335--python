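"""Generator contracts: determinism, CDS structure, mutations, read errors."""

import numpy as np
import pytest

from oracles import CODON_TABLE, hamming_n, rc

from alevar.synth import (
    CdsFeature,
    Contig,
    ContigSpec,
    Genome,
    GenomeSpec,
    MutationSpec,
    apply_mutations,
    build_genome,
    design_snps,
    diff_genomes,
    read_fasta,
    read_gff3,
    read_truth_tsv,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_gff3,
    write_truth_tsv,
)


class TestBuildGenome:
    def test_deterministic_for_fixed_seed(self, small_spec, small_genome):
        again = build_genome(small_spec)
        assert again == small_genome

    def test_different_seeds_differ(self, small_spec, small_genome):
        import dataclasses

        other = build_genome(dataclasses.replace(small_spec, seed=8))
        assert [c.sequence for c in other.contigs] != [
            c.sequence for c in small_genome.contigs
        ]

    def test_contig_and_cds_counts(self, small_genome):
        assert len(small_genome.contigs) == 2
        assert len(small_genome.features) == 4

    def test_cds_structure(self, small_genome):
        """Every CDS starts ATG, ends in a stop, has no internal stops."""
        for feat in small_genome.features:
            cds = small_genome.cds_sequence(feat)
            assert len(cds) % 3 == 0
            assert cds[:3] == "ATG"
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            assert CODON_TABLE[codons[-1]] == "*"
            assert all(CODON_TABLE[c] != "*" for c in codons[:-1])

    def test_cds_beyond_contig_rejected(self):
        spec = GenomeSpec(
            contigs=(ContigSpec("c1", 1000, "chromosome"),),
            cds=((("c1", 900, 1199, "+")),),
            seed=1,
        )
        with pytest.raises(ValueError, match="beyond contig end"):
            build_genome(spec)

    def test_overlapping_cds_same_strand_rejected(self):
        spec = GenomeSpec(
            contigs=(ContigSpec("c1", 2000, "chromosome"),),
            cds=(("c1", 100, 399, "+"), ("c1", 300, 599, "+")),
            seed=1,
        )
        with pytest.raises(ValueError, match="overlap"):
            build_genome(spec)

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError, match="1 kb"):
            GenomeSpec(contigs=(ContigSpec("c1", 500, "chromosome"),))


class TestApplyMutations:
    def test_snps_plus_replicon_loss(self, small_genome):
        snps = design_snps(small_genome, 1, 2, seed=3, contig_ids={"chr"})
        specs = snps + [MutationSpec(kind="replicon_loss", contig_id="pSMALL")]
        evolved = apply_mutations(small_genome, specs)
        assert [c.id for c in evolved.contigs] == ["chr"]
        wt = small_genome.contig("chr").sequence
        ev = evolved.contig("chr").sequence
        diffs = [i for i, (a, b) in enumerate(zip(wt, ev)) if a != b]
        assert len(diffs) == 3

    def test_empty_spec_list_is_identity(self, small_genome):
        assert apply_mutations(small_genome, []) == small_genome

    def test_input_untouched(self, small_genome):
        before = small_genome.contig("chr").sequence
        pos = 10
        ref = before[pos - 1]
        alt = "A" if ref != "A" else "C"
        apply_mutations(
            small_genome,
            [MutationSpec(kind="snp", contig_id="chr", position=pos, ref_base=ref, alt_base=alt)],
        )
        assert small_genome.contig("chr").sequence == before

    def test_ref_base_mismatch_rejected(self, small_genome):
        ref = small_genome.contig("chr").sequence[0]
        wrong = "A" if ref != "A" else "C"
        alt = "G" if wrong != "G" else "T"
        spec = MutationSpec(kind="snp", contig_id="chr", position=1, ref_base=wrong, alt_base=alt)
        with pytest.raises(ValueError, match="ref_base mismatch"):
            apply_mutations(small_genome, [spec])

    def test_replicon_loss_on_chromosome_rejected(self, small_genome):
        with pytest.raises(ValueError, match="plasmid"):
            apply_mutations(
                small_genome, [MutationSpec(kind="replicon_loss", contig_id="chr")]
            )

    def test_mutation_roundtrip_via_diff(self, small_genome):
        """apply_mutations then diff recovers the spec list exactly."""
        specs = design_snps(small_genome, 2, 3, seed=11, contig_ids={"chr"}) + [
            MutationSpec(kind="replicon_loss", contig_id="pSMALL")
        ]
        evolved = apply_mutations(small_genome, specs)
        recovered = diff_genomes(small_genome, evolved)
        assert sorted(recovered, key=repr) == sorted(specs, key=repr)


class TestDesignSnps:
    def test_requested_effects(self, small_genome):
        """Planted SNPs have the requested synonymous/nonsynonymous split."""
        specs = design_snps(small_genome, 2, 2, seed=5)
        assert len(specs) == 4
        evolved = apply_mutations(small_genome, specs)
        syn = nonsyn = 0
        for feat in small_genome.features:
            wt = small_genome.cds_sequence(feat)
            ev = evolved.cds_sequence(feat)
            for i in range(0, len(wt), 3):
                if wt[i : i + 3] != ev[i : i + 3]:
                    if CODON_TABLE[wt[i : i + 3]] == CODON_TABLE[ev[i : i + 3]]:
                        syn += 1
                    else:
                        nonsyn += 1
        assert (syn, nonsyn) == (2, 2)


class TestSimulateReads:
    def test_read_count_contract(self, small_genome):
        reads = simulate_reads(small_genome, depth=10, read_len=50, err_rate=0.0, seed=1)
        assert len(reads) == round(10 * 6000 / 50) + round(10 * 2000 / 50)

    def test_error_free_reads_match_origin(self, small_genome):
        reads = simulate_reads(small_genome, depth=2, read_len=60, err_rate=0.0, seed=2)
        seqs = {c.id: c.sequence for c in small_genome.contigs}
        for read in reads:
            cid, pos, strand = read.truth
            origin = seqs[cid][pos - 1 : pos - 1 + 60]
            expect = rc(origin) if strand == "-" else origin
            assert hamming_n(read.sequence, expect) == 0

    def test_substitution_rate_binomial(self, small_genome):
        """Observed error fraction within 3 SE of the nominal rate (1e6 bases)."""
        err = 0.01
        reads = simulate_reads(small_genome, depth=125, read_len=100, err_rate=err, seed=3)
        total = sum(len(r.sequence) for r in reads)
        assert total >= 1_000_000
        seqs = {c.id: c.sequence for c in small_genome.contigs}
        mism = 0
        for read in reads:
            cid, pos, strand = read.truth
            origin = seqs[cid][pos - 1 : pos - 1 + 100]
            expect = rc(origin) if strand == "-" else origin
            mism += hamming_n(read.sequence, expect)
        se = (err * (1 - err) / total) ** 0.5
        assert abs(mism / total - err) < 3 * se

    def test_deterministic(self, small_genome):
        a = simulate_reads(small_genome, depth=5, read_len=50, err_rate=0.01, seed=9)
        b = simulate_reads(small_genome, depth=5, read_len=50, err_rate=0.01, seed=9)
        assert a == b

    def test_read_len_longer_than_contig_rejected(self, small_genome):
        with pytest.raises(ValueError, match="shortest contig"):
            simulate_reads(small_genome, depth=1, read_len=2001, err_rate=0.0, seed=1)

    def test_err_rate_bounds(self, small_genome):
        with pytest.raises(ValueError, match="err_rate"):
            simulate_reads(small_genome, depth=1, read_len=50, err_rate=0.3, seed=1)


class TestFileIO:
    def test_fasta_gff_fastq_roundtrip_and_byte_determinism(self, small_genome, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(small_genome, p1)
        write_fasta(small_genome, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_fasta(p1)
        assert [c.sequence for c in back.contigs] == [c.sequence for c in small_genome.contigs]
        assert [c.replicon_class for c in back.contigs] == ["chromosome", "plasmid"]
        # line wrap at 70 columns
        body = [l for l in p1.read_text().splitlines() if not l.startswith(">")]
        assert max(len(l) for l in body) == 70

        gff = tmp_path / "f.gff3"
        write_gff3(small_genome, gff)
        feats = read_gff3(gff)
        assert tuple(feats) == small_genome.features

        reads = simulate_reads(small_genome, depth=1, read_len=50, err_rate=0.0, seed=4)
        q1, q2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq(reads, q1)
        write_fastq(reads, q2)
        assert q1.read_bytes() == q2.read_bytes()
        from alevar.synth import read_fastq

        back_reads = read_fastq(q1)
        assert [r.sequence for r in back_reads] == [r.sequence for r in reads]

    def test_truth_tsv_roundtrip(self, small_genome, tmp_path):
        specs = design_snps(small_genome, 1, 1, seed=2) + [
            MutationSpec(kind="replicon_loss", contig_id="pSMALL")
        ]
        path = tmp_path / "truth.tsv"
        write_truth_tsv(specs, path)
        assert read_truth_tsv(path) == specs
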