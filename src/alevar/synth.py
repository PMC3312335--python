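"""Synthetic genomes, evolved mutants, and error-bearing reads.

This module manufactures the inputs the analysis assumes: a wild-type
genome made of a large chromosome plus a dispensable plasmid replicon,
protein-coding genes laid out inside the contigs, an "evolved" genome
derived from it by point mutations and whole-replicon loss, and
fixed-length single-end reads with independent per-base substitution
errors. Ground truth (read origins, planted mutations) is carried
alongside so every downstream stage is testable without real data.

The error model is deliberately minimal: substitutions only, uniform
over the three alternative bases, no indels, no quality-dependent
structure. That matches the downstream caller, which is ungapped and
substitution-only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from ._dna import BASES, decode, encode, revcomp

__all__ = [
    "Contig",
    "CdsFeature",
    "Genome",
    "MutationSpec",
    "Read",
    "ReadSet",
    "GenomeSpec",
    "ContigSpec",
    "build_genome",
    "apply_mutations",
    "diff_genomes",
    "design_snps",
    "simulate_reads",
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_fastq",
    "read_fastq",
    "write_truth_tsv",
    "read_truth_tsv",
]

_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class Contig:
    """One replicon: a chromosome or a (dispensable) plasmid."""

    id: str
    sequence: str
    replicon_class: Literal["chromosome", "plasmid"]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"contig {self.id!r}: sequence must be over ACGT")
        if self.replicon_class not in ("chromosome", "plasmid"):
            raise ValueError(f"contig {self.id!r}: bad replicon_class {self.replicon_class!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding gene, 1-based inclusive coordinates."""

    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    locus_id: str
    product: str = "hypothetical protein"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"CDS {self.locus_id!r}: bad coordinates {self.start}..{self.end}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(f"CDS {self.locus_id!r}: length not divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.locus_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Genome:
    """Ordered contigs plus CDS annotations."""

    contigs: tuple[Contig, ...]
    features: tuple[CdsFeature, ...] = ()

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids")
        lengths = {c.id: len(c) for c in self.contigs}
        loci = [f.locus_id for f in self.features]
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus ids")
        by_strand: dict[tuple[str, str], list[CdsFeature]] = {}
        for f in self.features:
            if f.contig_id not in lengths:
                raise ValueError(f"CDS {f.locus_id!r}: unknown contig {f.contig_id!r}")
            if f.end > lengths[f.contig_id]:
                raise ValueError(f"CDS {f.locus_id!r}: extends beyond contig end")
            by_strand.setdefault((f.contig_id, f.strand), []).append(f)
        for (cid, strand), feats in by_strand.items():
            feats = sorted(feats, key=lambda f: f.start)
            for prev, nxt in zip(feats, feats[1:]):
                if nxt.start <= prev.end:
                    raise ValueError(
                        f"overlapping CDS on {cid}{strand}: {prev.locus_id} and {nxt.locus_id}"
                    )

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def cds_sequence(self, feature: CdsFeature) -> str:
        """Coding-strand sequence of a CDS (reverse-complemented for -)."""
        seq = self.contig(feature.contig_id).sequence[feature.start - 1 : feature.end]
        return revcomp(seq) if feature.strand == "-" else seq


@dataclass(frozen=True)
class MutationSpec:
    """A planted/true mutation: a SNP or the loss of a whole replicon."""

    kind: Literal["snp", "replicon_loss"]
    contig_id: str
    position: Optional[int] = None
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "snp":
            if self.position is None or self.ref_base is None or self.alt_base is None:
                raise ValueError("snp spec requires position, ref_base, alt_base")
            if self.ref_base not in BASES or self.alt_base not in BASES:
                raise ValueError("snp bases must be single ACGT nucleotides")
            if self.ref_base == self.alt_base:
                raise ValueError("alt_base must differ from ref_base")
        elif self.kind == "replicon_loss":
            if self.position is not None or self.ref_base is not None or self.alt_base is not None:
                raise ValueError("replicon_loss spec carries no position/bases")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")


@dataclass(frozen=True)
class Read:
    """A single-end read; truth is (contig_id, 1-based origin, strand) when simulated."""

    id: str
    sequence: str
    truth: Optional[tuple[str, int, str]] = None


@dataclass(frozen=True)
class ReadSet:
    reads: tuple[Read, ...]
    read_len: int

    def __post_init__(self) -> None:
        for r in self.reads:
            if len(r.sequence) != self.read_len:
                raise ValueError(f"read {r.id!r}: length {len(r.sequence)} != {self.read_len}")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigSpec:
    id: str
    length: int
    replicon_class: Literal["chromosome", "plasmid"]


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for a synthetic genome.

    CDSs are either given explicitly (``cds``: tuples of contig_id,
    start, end, strand) or laid out automatically: ``n_cds`` genes of
    ``cds_length`` bases are spread over the contigs in proportion to
    contig length, evenly spaced, at least ``cds_margin`` bases from
    each contig end, with strands drawn at random.

    Defaults approximate a Streptomyces-like replicon structure at desk
    scale: 200 kb chromosome + 50 kb dispensable plasmid, GC 0.72.
    """

    contigs: tuple[ContigSpec, ...] = (
        ContigSpec("chromosome", 200_000, "chromosome"),
        ContigSpec("pPLASMID", 50_000, "plasmid"),
    )
    gc: float = 0.72
    n_cds: int = 10
    cds_length: int = 900
    cds_margin: int = 500
    cds: Optional[tuple[tuple[str, int, int, str], ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("at least one contig required")
        for c in self.contigs:
            if c.length < 1000:
                raise ValueError(f"contig {c.id!r}: length must be >= 1 kb")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.cds_length % 3 != 0 or self.cds_length < 9:
            raise ValueError("cds_length must be a multiple of 3, >= 9")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _random_coding(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    n_internal = length // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_internal + 1:
        codon = decode(_random_sequence(rng, 3, gc))
        if codon not in _STOP_CODONS:
            codons.append(codon)
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def _auto_layout(spec: GenomeSpec, rng: np.random.Generator) -> list[tuple[str, int, int, str]]:
    total = sum(c.length for c in spec.contigs)
    # proportional apportionment, largest remainder
    quotas = [spec.n_cds * c.length / total for c in spec.contigs]
    counts = [int(q) for q in quotas]
    for _ in range(spec.n_cds - sum(counts)):
        i = max(range(len(quotas)), key=lambda j: quotas[j] - counts[j])
        counts[i] += 1
    layout = []
    for cspec, m in zip(spec.contigs, counts):
        if m == 0:
            continue
        usable = cspec.length - 2 * spec.cds_margin
        if usable < m * spec.cds_length:
            raise ValueError(f"contig {cspec.id!r} too short for {m} CDS of {spec.cds_length} bp")
        pitch = usable // m
        for i in range(m):
            start = spec.cds_margin + i * pitch + 1
            end = start + spec.cds_length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            layout.append((cspec.id, start, end, strand))
    return layout


def build_genome(spec: GenomeSpec) -> Genome:
    """Generate a genome from a spec, deterministically for a fixed seed.

    Every CDS begins with ATG and ends with a stop codon on its own
    strand; internal codons are non-stop. Raises on CDSs that fall
    outside their contig or overlap on the same strand.
    """
    rng = np.random.default_rng(spec.seed)
    seqs = {c.id: _random_sequence(rng, c.length, spec.gc) for c in spec.contigs}
    layout = list(spec.cds) if spec.cds is not None else _auto_layout(spec, rng)

    features = []
    lengths = {c.id: c.length for c in spec.contigs}
    for i, (cid, start, end, strand) in enumerate(layout):
        if cid not in lengths:
            raise ValueError(f"CDS on unknown contig {cid!r}")
        if end > lengths[cid]:
            raise ValueError(f"CDS {cid}:{start}-{end} extends beyond contig end")
        coding = _random_coding(rng, end - start + 1, spec.gc)
        if strand == "-":
            coding = revcomp(coding)
        seqs[cid][start - 1 : end] = encode(coding)
        features.append(
            CdsFeature(
                contig_id=cid,
                start=start,
                end=end,
                strand=strand,  # type: ignore[arg-type]
                locus_id=f"{cid}_cds{i + 1:04d}",
                product="hypothetical protein",
            )
        )

    contigs = tuple(
        Contig(c.id, decode(seqs[c.id]), c.replicon_class) for c in spec.contigs
    )
    return Genome(contigs=contigs, features=tuple(features))


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def apply_mutations(genome: Genome, specs: Sequence[MutationSpec]) -> Genome:
    """Return a new genome with SNPs substituted and lost replicons removed.

    The input genome is untouched. A SNP spec whose ref_base disagrees
    with the genome is rejected — this guards the integrity of the
    truth table. replicon_loss is only legal on plasmid contigs.
    """
    seqs = {c.id: bytearray(c.sequence, "ascii") for c in genome.contigs}
    classes = {c.id: c.replicon_class for c in genome.contigs}
    lost: set[str] = set()
    for spec in specs:
        if spec.contig_id not in seqs:
            raise ValueError(f"mutation on unknown contig {spec.contig_id!r}")
        if spec.kind == "replicon_loss":
            if classes[spec.contig_id] != "plasmid":
                raise ValueError(f"replicon_loss only allowed on plasmids, not {spec.contig_id!r}")
            lost.add(spec.contig_id)
        else:
            assert spec.position is not None
            seq = seqs[spec.contig_id]
            if not (1 <= spec.position <= len(seq)):
                raise ValueError(f"SNP position {spec.position} outside contig {spec.contig_id!r}")
            have = chr(seq[spec.position - 1])
            if have != spec.ref_base:
                raise ValueError(
                    f"ref_base mismatch at {spec.contig_id}:{spec.position}: "
                    f"genome has {have}, spec says {spec.ref_base}"
                )
            seq[spec.position - 1] = ord(spec.alt_base)  # type: ignore[arg-type]

    contigs = tuple(
        Contig(c.id, seqs[c.id].decode("ascii"), c.replicon_class)
        for c in genome.contigs
        if c.id not in lost
    )
    features = tuple(f for f in genome.features if f.contig_id not in lost)
    return Genome(contigs=contigs, features=features)


def diff_genomes(wild: Genome, evolved: Genome) -> list[MutationSpec]:
    """Recover the mutation list separating two genomes.

    Contigs present in the wild type but absent from the evolved genome
    are reported as replicon_loss; same-length contigs are compared
    base-by-base for SNPs. The result round-trips apply_mutations.
    """
    evolved_ids = {c.id for c in evolved.contigs}
    out: list[MutationSpec] = []
    for c in wild.contigs:
        if c.id not in evolved_ids:
            out.append(MutationSpec(kind="replicon_loss", contig_id=c.id))
            continue
        other = evolved.contig(c.id)
        if len(other) != len(c):
            raise ValueError(f"contig {c.id!r}: length change is not a SNP set")
        a = encode(c.sequence)
        b = encode(other.sequence)
        for pos in np.nonzero(a != b)[0]:
            out.append(
                MutationSpec(
                    kind="snp",
                    contig_id=c.id,
                    position=int(pos) + 1,
                    ref_base=c.sequence[pos],
                    alt_base=other.sequence[pos],
                )
            )
    return out


def design_snps(
    genome: Genome,
    n_synonymous: int,
    n_nonsynonymous: int,
    seed: int = 0,
    contig_ids: Optional[set[str]] = None,
) -> list[MutationSpec]:
    """Pick coding SNPs with prescribed effects from a genome's CDSs.

    Draws codons (never the start or stop codon, at most one SNP per
    CDS until all CDSs are used) and searches for a substitution whose
    translation effect matches the request; nonsynonymous picks avoid
    creating stop codons. Positions and bases are reported in genome
    forward-strand coordinates. ``contig_ids`` restricts the eligible
    CDSs (e.g. to replicons that the evolved strain retains).
    """
    rng = np.random.default_rng(seed)
    wanted = ["syn"] * n_synonymous + ["nonsyn"] * n_nonsynonymous
    if not wanted:
        return []
    features = tuple(
        f for f in genome.features if contig_ids is None or f.contig_id in contig_ids
    )
    if not features:
        raise ValueError("no eligible CDS features to place SNPs in")
    out: list[MutationSpec] = []
    used_cds: set[str] = set()
    attempts = 0
    while wanted:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not design the requested SNPs")
        pool = [f for f in features if f.locus_id not in used_cds] or list(features)
        feat = pool[rng.integers(len(pool))]
        cds_seq = genome.cds_sequence(feat)
        n_codons = len(cds_seq) // 3
        codon_idx = int(rng.integers(1, n_codons - 1))  # skip start & stop
        codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
        ref_aa = str(Seq(codon).translate())
        offsets = list(rng.permutation(3))
        found = None
        for off in offsets:
            for alt in rng.permutation(list("ACGT")):
                if alt == codon[off]:
                    continue
                alt_codon = codon[:off] + alt + codon[off + 1 :]
                alt_aa = str(Seq(alt_codon).translate())
                if alt_aa == "*":
                    continue
                effect = "syn" if alt_aa == ref_aa else "nonsyn"
                if effect == wanted[0]:
                    found = (off, alt)
                    break
            if found:
                break
        if not found:
            continue
        off, alt = found
        off = int(off)
        alt = str(alt)
        cds_pos = codon_idx * 3 + off + 1  # 1-based within CDS
        ref_cds_base = cds_seq[cds_pos - 1]
        if feat.strand == "+":
            pos = int(feat.start + cds_pos - 1)
            ref_b, alt_b = ref_cds_base, alt
        else:
            pos = int(feat.end - cds_pos + 1)
            ref_b, alt_b = revcomp(ref_cds_base), revcomp(alt)
        if any(m.kind == "snp" and m.contig_id == feat.contig_id and m.position == pos for m in out):
            continue
        out.append(
            MutationSpec(
                kind="snp", contig_id=feat.contig_id, position=pos,
                ref_base=ref_b, alt_base=alt_b,
            )
        )
        used_cds.add(feat.locus_id)
        wanted.pop(0)
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Genome,
    depth: float,
    read_len: int,
    err_rate: float,
    seed: int,
) -> ReadSet:
    """Uniform-coverage single-end reads with iid substitution errors.

    Per contig, round(depth x length / read_len) reads are drawn with
    origins uniform over valid start positions and strands uniform;
    each base is substituted, independently with probability err_rate,
    by one of the three other bases chosen uniformly. Deterministic for
    a fixed seed. Truth (origin contig, 1-based start, strand) is
    recorded on every read.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0.0 <= err_rate < 0.25):
        raise ValueError("err_rate must be in [0, 0.25)")
    shortest = min(len(c) for c in genome.contigs)
    if read_len > shortest:
        raise ValueError(f"read_len {read_len} exceeds shortest contig ({shortest} bp)")

    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for contig in genome.contigs:
        n = int(round(depth * len(contig) / read_len))
        if n == 0:
            continue
        codes = encode(contig.sequence)
        starts = rng.integers(0, len(contig) - read_len + 1, size=n)
        strands = rng.integers(0, 2, size=n)  # 0 = +, 1 = -
        mat = codes[starts[:, None] + np.arange(read_len)]
        # strand: reverse complement the minus-strand rows
        minus = strands == 1
        mat[minus] = 3 - mat[minus, ::-1]
        # substitution errors: shift by 1..3 mod 4
        if err_rate > 0:
            err_mask = rng.random(mat.shape) < err_rate
            shifts = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat[err_mask] = (mat[err_mask] + shifts[err_mask]) % 4
        for i in range(n):
            reads.append(
                Read(
                    id=f"{contig.id}_r{i + 1:06d}",
                    sequence=decode(mat[i]),
                    truth=(contig.id, int(starts[i]) + 1, "-" if minus[i] else "+"),
                )
            )
    return ReadSet(reads=tuple(reads), read_len=read_len)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_fasta(genome: Genome, path: str | Path) -> None:
    """FASTA wrapped at 70 columns; replicon class kept in the description."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description=f"replicon={c.replicon_class}")
        for c in genome.contigs
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(records)


def read_fasta(path: str | Path) -> Genome:
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cls = "chromosome"
        for token in rec.description.split():
            if token.startswith("replicon="):
                cls = token.split("=", 1)[1]
        contigs.append(Contig(rec.id, str(rec.seq).upper(), cls))  # type: ignore[arg-type]
    return Genome(contigs=tuple(contigs))


def write_gff3(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in genome.contigs:
            fh.write(f"##sequence-region {c.id} 1 {len(c)}\n")
        for f in genome.features:
            attrs = f"ID={f.locus_id};product={f.product}"
            fh.write(
                f"{f.contig_id}\talevar\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[CdsFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            feats.append(
                CdsFeature(
                    contig_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],  # type: ignore[arg-type]
                    locus_id=attrs.get("ID", f"{cols[0]}:{cols[3]}-{cols[4]}"),
                    product=attrs.get("product", ""),
                )
            )
    return feats


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """FASTQ with constant quality 'I' (Phred+33, Q40)."""
    with open(path, "w") as fh:
        qual = "I" * reads.read_len
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> ReadSet:
    reads = []
    read_len = None
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        if read_len is None:
            read_len = len(seq)
        reads.append(Read(id=rec.id, sequence=seq))
    if read_len is None:
        raise ValueError(f"no reads in {path}")
    return ReadSet(reads=tuple(reads), read_len=read_len)


def write_truth_tsv(specs: Sequence[MutationSpec], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["kind", "contig", "position", "ref", "alt"])
        for m in specs:
            w.writerow([
                m.kind, m.contig_id,
                m.position if m.position is not None else ".",
                m.ref_base or ".", m.alt_base or ".",
            ])


def read_truth_tsv(path: str | Path) -> list[MutationSpec]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["kind"] == "replicon_loss":
                out.append(MutationSpec(kind="replicon_loss", contig_id=row["contig"]))
            else:
                out.append(
                    MutationSpec(
                        kind="snp", contig_id=row["contig"],
                        position=int(row["position"]),
                        ref_base=row["ref"], alt_base=row["alt"],
                    )
                )
    return out
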