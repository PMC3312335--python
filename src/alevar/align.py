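"""Ungapped read alignment against a concatenated multi-contig reference.

The reference contigs are concatenated into one sequence (the way draft
assemblies of hundreds of contigs are prepared for alignment), with an
exact bijective map between global and per-contig coordinates. Reads
are placed by a k-mer seed index plus full-read Hamming verification —
deterministic and checkable against a brute-force scan — and the
mismatch budget is escalated iteratively from 0 up to a cap (default
5): a read is stamped with the first (lowest) level that admits it,
so its iteration level always equals its mismatch count.

Placement policy (documented choices, not dictated by the procedure):
multi-best reads are ambiguous and discarded, placements spanning a
junction between concatenated contigs are rejected, and N bases
mismatch every reference base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._dna import encode, revcomp
from .synth import Contig, Read, ReadSet

__all__ = [
    "ConcatenatedReference",
    "AlignmentRecord",
    "AlignStatus",
    "IterativeResult",
    "build_reference",
    "align_read",
    "align_iterative",
    "write_sam",
]

logger = logging.getLogger(__name__)

DEFAULT_SEED_K = 12
DEFAULT_MAX_LEVEL = 5


class AlignStatus(Enum):
    ALIGNED = "aligned"
    AMBIGUOUS = "ambiguous"
    UNALIGNED = "unaligned"


@dataclass(frozen=True)
class AlignmentRecord:
    """A unique ungapped placement of one read."""

    read_id: str
    contig_id: str
    position: int  # 1-based leftmost on the contig forward strand
    strand: str  # "+" or "-"
    mismatch_count: int
    iteration_level: int
    sequence: str  # read bases as sequenced (original orientation)


@dataclass
class ConcatenatedReference:
    """Contigs joined end-to-end with exact coordinate maps."""

    contigs: tuple[Contig, ...]
    _codes: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids")
        self.offsets: dict[str, int] = {}
        self.lengths: dict[str, int] = {}
        off = 0
        for c in self.contigs:
            self.offsets[c.id] = off
            self.lengths[c.id] = len(c)
            off += len(c)
        self.total_length = off
        self._bounds = np.cumsum([0] + [len(c) for c in self.contigs])
        self._ids = ids

    @property
    def sequence(self) -> str:
        return "".join(c.sequence for c in self.contigs)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = np.concatenate([encode(c.sequence) for c in self.contigs])
        return self._codes

    def to_local(self, global_pos: int) -> tuple[str, int]:
        """0-based global position -> (contig_id, 1-based local position)."""
        if not (0 <= global_pos < self.total_length):
            raise ValueError(f"global position {global_pos} out of range")
        i = int(np.searchsorted(self._bounds, global_pos, side="right")) - 1
        return self._ids[i], global_pos - int(self._bounds[i]) + 1

    def to_global(self, contig_id: str, local_pos: int) -> int:
        """(contig_id, 1-based local position) -> 0-based global position."""
        if not (1 <= local_pos <= self.lengths[contig_id]):
            raise ValueError(f"position {local_pos} outside contig {contig_id!r}")
        return self.offsets[contig_id] + local_pos - 1

    def fits_in_contig(self, global_start: int, length: int) -> bool:
        """True if [global_start, global_start+length) stays inside one contig."""
        if global_start < 0 or global_start + length > self.total_length:
            return False
        i = int(np.searchsorted(self._bounds, global_start, side="right")) - 1
        return global_start + length <= int(self._bounds[i + 1])

    def seed_index(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(sorted k-mer codes, positions in sorted order), built lazily."""
        if k not in self._index:
            codes = self.codes.astype(np.int64)
            n = self.total_length - k + 1
            if n <= 0:
                raise ValueError(f"reference shorter than seed size {k}")
            kmer = np.zeros(n, dtype=np.int64)
            for j in range(k):
                kmer = (kmer << 2) | codes[j : j + n]
            order = np.argsort(kmer, kind="stable")
            self._index[k] = (kmer[order], order.astype(np.int64))
        return self._index[k]


def build_reference(contigs: Sequence[Contig]) -> ConcatenatedReference:
    """Concatenate contigs; offsets are the cumulative preceding lengths."""
    if not contigs:
        raise ValueError("at least one contig required")
    return ConcatenatedReference(contigs=tuple(contigs))


# ---------------------------------------------------------------------------
# Placement search
# ---------------------------------------------------------------------------

def _seed_candidates(
    rcodes: np.ndarray, ref: ConcatenatedReference, k: int
) -> set[int]:
    """Global start positions suggested by every non-overlapping k-mer seed.

    With floor(L/k) seeds, pigeonhole guarantees that any placement with
    fewer than floor(L/k) mismatches shares at least one exact seed.
    Seeds containing N are skipped (they can never match the reference).
    """
    length = len(rcodes)
    sorted_codes, order = ref.seed_index(k)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    cands: set[int] = set()
    max_start = ref.total_length - length
    for off in range(0, length - k + 1, k):
        window = rcodes[off : off + k]
        if (window == 4).any():
            continue
        q = int(window.astype(np.int64) @ pow4)
        lo = int(np.searchsorted(sorted_codes, q, side="left"))
        hi = int(np.searchsorted(sorted_codes, q, side="right"))
        for pos in order[lo:hi]:
            g = int(pos) - off
            if 0 <= g <= max_start:
                cands.add(g)
    return cands


def _best_placements(
    read_seq: str,
    ref: ConcatenatedReference,
    max_mm: int,
    k: int,
) -> tuple[int, list[tuple[int, str]]]:
    """Minimum Hamming distance <= max_mm and all placements achieving it.

    Returns (distance, [(global_start, strand), ...]); distance is
    max_mm + 1 with an empty list when nothing is within budget.
    Junction-spanning placements are excluded. Falls back to an
    exhaustive sliding-window scan when the read is too short for the
    seed guarantee to cover max_mm mismatches.
    """
    length = len(read_seq)
    refcodes = ref.codes
    best = max_mm + 1
    hits: list[tuple[int, str]] = []
    exhaustive = (length // k) < max_mm + 1
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        rcodes = encode(seq)
        if exhaustive:
            if ref.total_length < length:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(refcodes, length)
            dists = (windows != rcodes).sum(axis=1)
            cand_iter = ((int(g), int(d)) for g, d in enumerate(dists) if d <= max_mm)
        else:
            cand_iter = (
                (g, int(np.count_nonzero(refcodes[g : g + length] != rcodes)))
                for g in _seed_candidates(rcodes, ref, k)
            )
        for g, d in cand_iter:
            if d > max_mm or not ref.fits_in_contig(g, length):
                continue
            if d < best:
                best = d
                hits = [(g, strand)]
            elif d == best:
                hits.append((g, strand))
    return best, hits


def align_read(
    read: Read,
    ref: ConcatenatedReference,
    max_mm: int,
    k: int = DEFAULT_SEED_K,
) -> tuple[AlignStatus, Optional[AlignmentRecord]]:
    """Place one read at its minimum-Hamming position within a budget.

    ALIGNED with a record when the minimum distance <= max_mm is
    achieved at exactly one (position, strand); AMBIGUOUS when several
    placements tie (including plus/minus ties at one position);
    UNALIGNED when nothing fits the budget.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    if len(read.sequence) < k:
        raise ValueError(f"read {read.id!r} shorter than seed size {k}")
    best, hits = _best_placements(read.sequence, ref, max_mm, k)
    # a palindromic read may hit one position on both strands: that is a tie
    if len(hits) > 1:
        return AlignStatus.AMBIGUOUS, None
    if not hits:
        return AlignStatus.UNALIGNED, None
    g, strand = hits[0]
    contig_id, local = ref.to_local(g)
    return AlignStatus.ALIGNED, AlignmentRecord(
        read_id=read.id,
        contig_id=contig_id,
        position=local,
        strand=strand,
        mismatch_count=best,
        iteration_level=best,
        sequence=read.sequence,
    )


@dataclass(frozen=True)
class IterativeResult:
    alignments: tuple[AlignmentRecord, ...]
    leftovers: tuple[Read, ...]
    ambiguous: tuple[Read, ...]
    per_level: dict[int, int]  # iteration level -> reads aligned at that level


def align_iterative(
    reads: ReadSet | Iterable[Read],
    ref: ConcatenatedReference,
    max_level: int = DEFAULT_MAX_LEVEL,
    k: int = DEFAULT_SEED_K,
) -> IterativeResult:
    """Escalate the mismatch budget 0..max_level, re-feeding unaligned reads.

    A read uniquely placeable at minimum distance m is admitted at the
    first level reaching m, so it is stamped iteration_level = m and is
    excluded from later levels. Reads whose minimum is tied between
    several placements become ambiguous at that level and are dropped
    (logged, never carried forward). Leftovers are the reads that no
    level could place.
    """
    if max_level < 0:
        raise ValueError("max_level must be >= 0")
    alignments: list[AlignmentRecord] = []
    ambiguous: list[Read] = []
    leftovers: list[Read] = []
    per_level: dict[int, int] = {}
    for read in reads:
        status, rec = align_read(read, ref, max_mm=max_level, k=k)
        if status is AlignStatus.ALIGNED:
            assert rec is not None
            alignments.append(rec)
            per_level[rec.iteration_level] = per_level.get(rec.iteration_level, 0) + 1
        elif status is AlignStatus.AMBIGUOUS:
            ambiguous.append(read)
        else:
            leftovers.append(read)
    logger.info(
        "align_iterative: %d aligned, %d ambiguous (discarded), %d leftover",
        len(alignments), len(ambiguous), len(leftovers),
    )
    return IterativeResult(
        alignments=tuple(alignments),
        leftovers=tuple(leftovers),
        ambiguous=tuple(ambiguous),
        per_level=per_level,
    )


# ---------------------------------------------------------------------------
# SAM output (minimal subset)
# ---------------------------------------------------------------------------

def write_sam(
    result: IterativeResult,
    ref: ConcatenatedReference,
    path: str | Path,
) -> None:
    """Minimal SAM: @SQ per contig; NM:i mismatches, XI:i iteration level.

    Aligned records carry flag 0/16 with CIGAR <len>M and the SEQ field
    reverse-complemented for minus-strand placements (SAM stores the
    forward-strand image); leftovers are emitted unmapped (flag 4).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in ref.contigs:
            fh.write(f"@SQ\tSN:{c.id}\tLN:{len(c)}\n")
        for rec in result.alignments:
            flag = 16 if rec.strand == "-" else 0
            seq = revcomp(rec.sequence) if rec.strand == "-" else rec.sequence
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.contig_id}\t{rec.position}\t255\t"
                f"{len(rec.sequence)}M\t*\t0\t0\t{seq}\t*\t"
                f"NM:i:{rec.mismatch_count}\tXI:i:{rec.iteration_level}\n"
            )
        for read in result.leftovers:
            fh.write(f"{read.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.sequence}\t*\n")
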