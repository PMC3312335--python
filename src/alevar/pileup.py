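"""Per-base fold coverage and count-ratio SNP calling.

The pileup tallies, for every reference position of every contig
(zero-depth columns included), how many aligned reads cover it and
which base each contributes, with minus-strand reads complemented back
onto forward-strand coordinates. On top of the pileup sits the
polymorphism rule used for the strain comparison: a site is called
variant when the top non-reference base count strictly exceeds
``factor`` times the reference base count (default factor 2) at a
total depth of at least ``min_depth`` (default 10x).

Interpretation choices exposed as configuration: the "observed
nucleotide count" is the single most frequent non-reference base by
default (mode="top"); mode="pooled" sums all non-reference bases
instead. N bases never contribute to either count; ties among
non-reference bases yield no call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from ._dna import BASES, encode, revcomp
from .align import AlignmentRecord, ConcatenatedReference

__all__ = [
    "PileupColumn",
    "VariantCall",
    "Pileup",
    "compute_pileup",
    "call_variants",
    "write_pileup_tsv",
    "write_vcf",
]


@dataclass(frozen=True)
class PileupColumn:
    contig_id: str
    position: int  # 1-based
    depth: int
    counts: dict[str, int]  # A/C/G/T/N -> count; sums to depth


@dataclass(frozen=True)
class VariantCall:
    contig_id: str
    position: int  # 1-based
    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int
    depth: int
    passed: bool
    filter: str  # "PASS", "lowdepth" or "ratio"


class Pileup:
    """Dense per-position base counts over a concatenated reference.

    Stored as a (5, total_length) matrix in A/C/G/T/N row order; the
    column API materialises PileupColumn objects on demand.
    """

    def __init__(self, ref: ConcatenatedReference, counts: np.ndarray):
        if counts.shape != (5, ref.total_length):
            raise ValueError("counts matrix does not match reference length")
        self.ref = ref
        self.counts = counts
        self.depth = counts.sum(axis=0)

    def contig_slice(self, contig_id: str) -> tuple[int, int]:
        off = self.ref.offsets[contig_id]
        return off, off + self.ref.lengths[contig_id]

    def column(self, contig_id: str, position: int) -> PileupColumn:
        g = self.ref.to_global(contig_id, position)
        col = self.counts[:, g]
        return PileupColumn(
            contig_id=contig_id,
            position=position,
            depth=int(self.depth[g]),
            counts={b: int(col[i]) for i, b in enumerate(BASES + "N")},
        )

    def iter_columns(self) -> Iterator[PileupColumn]:
        for contig in self.ref.contigs:
            for pos in range(1, len(contig) + 1):
                yield self.column(contig.id, pos)


def compute_pileup(
    alignments: Sequence[AlignmentRecord],
    ref: ConcatenatedReference,
) -> Pileup:
    """Tally aligned read bases at forward-strand coordinates.

    Minus-strand reads contribute their reverse complement. Every
    position of every contig has a column, so untouched replicons show
    up as zero-depth stretches. An alignment that would overrun its
    contig indicates an upstream bug and is rejected.
    """
    n = ref.total_length
    counts = np.zeros((5, n), dtype=np.int64)
    if alignments:
        flat_pos: list[np.ndarray] = []
        flat_base: list[np.ndarray] = []
        for rec in alignments:
            length = len(rec.sequence)
            if rec.position + length - 1 > ref.lengths[rec.contig_id]:
                raise ValueError(
                    f"alignment of {rec.read_id!r} overruns contig {rec.contig_id!r}"
                )
            g = ref.to_global(rec.contig_id, rec.position)
            seq = revcomp(rec.sequence) if rec.strand == "-" else rec.sequence
            flat_pos.append(np.arange(g, g + length, dtype=np.int64))
            flat_base.append(encode(seq).astype(np.int64))
        pos = np.concatenate(flat_pos)
        base = np.concatenate(flat_base)
        np.add.at(counts.reshape(-1), base * n + pos, 1)
    return Pileup(ref, counts)


def call_variants(
    pileup: Pileup,
    min_depth: int = 10,
    factor: float = 2.0,
    mode: str = "top",
    emit_all: bool = False,
) -> list[VariantCall]:
    """Apply the count-ratio polymorphism rule to every column.

    A candidate site has at least one non-reference ACGT base observed.
    It passes when total depth >= min_depth and the observed count
    (top non-reference base, or the pooled non-reference sum with
    mode="pooled") is strictly greater than factor x the reference base
    count. A zero reference count with any alternative observations at
    sufficient depth therefore passes. Sites whose two top
    non-reference bases tie are never called. Only passing calls are
    returned unless emit_all is set.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if factor <= 0:
        raise ValueError("factor must be positive")
    if mode not in ("top", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")

    ref = pileup.ref
    refcodes = ref.codes.astype(np.int64)
    acgt = pileup.counts[:4].copy()  # (4, n), N excluded throughout
    n = ref.total_length
    cols = np.arange(n)
    ref_count = acgt[refcodes, cols]
    nonref = acgt.copy()
    nonref[refcodes, cols] = -1  # mask the reference base out of the argmax
    alt_code = nonref.argmax(axis=0)
    top_count = nonref.max(axis=0)
    # tie among non-reference bases: top count achieved more than once
    tie = (nonref == top_count[None, :]).sum(axis=0) > 1
    observed = top_count if mode == "top" else acgt.sum(axis=0) - ref_count
    depth = pileup.depth

    candidate = (top_count > 0) & ~tie
    ratio_ok = observed > factor * ref_count
    depth_ok = depth >= min_depth
    passed = candidate & ratio_ok & depth_ok
    wanted = candidate if emit_all else passed

    calls: list[VariantCall] = []
    for g in np.nonzero(wanted)[0]:
        contig_id, local = ref.to_local(int(g))
        if not depth_ok[g]:
            filt = "lowdepth"
        elif not ratio_ok[g]:
            filt = "ratio"
        else:
            filt = "PASS"
        calls.append(
            VariantCall(
                contig_id=contig_id,
                position=local,
                ref_base=BASES[refcodes[g]],
                alt_base=BASES[alt_code[g]],
                ref_count=int(ref_count[g]),
                alt_count=int(observed[g]),
                depth=int(depth[g]),
                passed=bool(passed[g]),
                filter=filt,
            )
        )
    return calls


def write_pileup_tsv(pileup: Pileup, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tdepth\tA\tC\tG\tT\tN\n")
        for contig in pileup.ref.contigs:
            lo, hi = pileup.contig_slice(contig.id)
            block = pileup.counts[:, lo:hi]
            depth = pileup.depth[lo:hi]
            for i in range(hi - lo):
                a, c, g, t, nn = (int(block[j, i]) for j in range(5))
                fh.write(f"{contig.id}\t{i + 1}\t{int(depth[i])}\t{a}\t{c}\t{g}\t{t}\t{nn}\n")


def write_vcf(
    calls: Sequence[VariantCall],
    ref: ConcatenatedReference,
    path: str | Path,
) -> None:
    """VCF v4.2 with DP/RO/AO info and PASS/lowdepth/ratio filters."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=alevar\n")
        for c in ref.contigs:
            fh.write(f"##contig=<ID={c.id},length={len(c)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference base count">\n')
        fh.write('##INFO=<ID=AO,Number=1,Type=Integer,Description="Observed alternative count">\n')
        fh.write('##FILTER=<ID=lowdepth,Description="Total depth below cutoff">\n')
        fh.write('##FILTER=<ID=ratio,Description="Alt count not above factor x ref count">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in calls:
            fh.write(
                f"{v.contig_id}\t{v.position}\t.\t{v.ref_base}\t{v.alt_base}\t.\t"
                f"{v.filter}\tDP={v.depth};RO={v.ref_count};AO={v.alt_count}\n"
            )
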