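"""Replicon presence from coverage, and in-silico PCR verification.

A whole-replicon loss (e.g. a dispensable megaplasmid dropped during
laboratory evolution) shows up in resequencing as a contig with
negligible read coverage. Each contig is classified from its breadth
of coverage — the fraction of positions touched by at least one read:
``absent`` below the absent threshold (default 0.05), ``present`` at
or above the present threshold (default 0.90), ``partial`` in between
(a replicon of which only a portion is retained). The thresholds are
configurable; the defaults are this package's operational reading of
"negligible coverage".

The in-silico PCR emulates the amplicon presence/absence assay used to
confirm a replicon loss: a primer pair yields a product when the
forward primer matches exactly on one strand and the reverse primer's
reverse complement matches exactly downstream on the same strand,
within a maximum product length. Matching is exact — no mismatches,
no degenerate bases, no thermodynamics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from ._dna import revcomp
from .pileup import Pileup
from .synth import Genome

__all__ = [
    "RepliconStatus",
    "RepliconThresholds",
    "PrimerPair",
    "Amplicon",
    "replicon_summary",
    "insilico_pcr",
    "design_primer_pairs",
    "write_replicon_tsv",
    "write_amplicon_tsv",
    "read_primers_tsv",
    "write_primers_tsv",
]


@dataclass(frozen=True)
class RepliconThresholds:
    absent_below: float = 0.05
    present_at_least: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 <= self.absent_below < self.present_at_least <= 1.0):
            raise ValueError("need 0 <= absent_below < present_at_least <= 1")

    def classify(self, breadth: float) -> str:
        if breadth < self.absent_below:
            return "absent"
        if breadth >= self.present_at_least:
            return "present"
        return "partial"


@dataclass(frozen=True)
class RepliconStatus:
    contig_id: str
    replicon_class: str
    length: int
    mean_depth: float
    breadth: float  # fraction of positions with depth >= 1
    classification: str  # present / partial / absent


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_product: int

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if len(primer) < 15:
                raise ValueError(f"primer pair {self.name!r}: primers must be >= 15 bases")
            if set(primer) - set("ACGT"):
                raise ValueError(f"primer pair {self.name!r}: primers must be over ACGT")
        if self.max_product <= len(self.forward) + len(self.reverse):
            raise ValueError(
                f"primer pair {self.name!r}: max_product must exceed the primer lengths"
            )


@dataclass(frozen=True)
class Amplicon:
    name: str
    contig_id: str
    start: int  # 1-based, leftmost base of the product on the forward strand
    end: int  # 1-based, rightmost base
    product_length: int
    strand: str  # strand the forward primer annealed to


def replicon_summary(
    pileup: Pileup,
    genome: Genome | None = None,
    thresholds: RepliconThresholds = RepliconThresholds(),
) -> list[RepliconStatus]:
    """Mean depth, breadth and presence class per replicon.

    The pileup must cover every position (zero-depth columns included),
    which the dense Pileup guarantees. When a genome layout is given,
    its contig set must match the pileup's reference and supplies the
    replicon classes.
    """
    classes = {c.id: c.replicon_class for c in pileup.ref.contigs}
    if genome is not None:
        layout = {c.id: c.replicon_class for c in genome.contigs}
        unknown = set(classes) - set(layout)
        if unknown:
            raise ValueError(f"pileup contigs missing from genome layout: {sorted(unknown)}")
        classes.update(layout)
    out = []
    for contig in pileup.ref.contigs:
        lo, hi = pileup.contig_slice(contig.id)
        depth = pileup.depth[lo:hi]
        length = hi - lo
        breadth = float((depth >= 1).sum() / length)
        out.append(
            RepliconStatus(
                contig_id=contig.id,
                replicon_class=classes[contig.id],
                length=length,
                mean_depth=float(depth.sum() / length),
                breadth=breadth,
                classification=thresholds.classify(breadth),
            )
        )
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def insilico_pcr(genome: Genome, pairs: Sequence[PrimerPair]) -> list[Amplicon]:
    """All exact-match products of each primer pair, both orientations.

    On the forward strand the product runs from the start of a forward
    primer site to the end of a downstream reverse-complemented reverse
    primer site; the mirrored arrangement (forward primer annealing to
    the minus strand) is searched symmetrically. Product length is
    bounded by the pair's max_product; primer sites must not overlap.
    """
    out: list[Amplicon] = []
    for pair in pairs:
        for contig in genome.contigs:
            seq = contig.sequence
            # forward primer on +: fwd ... revcomp(reverse)
            # forward primer on -: reverse ... revcomp(fwd)
            for strand, left, right in (
                ("+", pair.forward, revcomp(pair.reverse)),
                ("-", pair.reverse, revcomp(pair.forward)),
            ):
                right_sites = _find_all(seq, right)
                if not right_sites:
                    continue
                for i in _find_all(seq, left):
                    for j in right_sites:
                        if j < i + len(left):
                            continue  # reverse site must lie fully downstream
                        product = j + len(right) - i
                        if product > pair.max_product:
                            break  # right_sites ascending: all later ones longer
                        out.append(
                            Amplicon(
                                name=pair.name,
                                contig_id=contig.id,
                                start=i + 1,
                                end=j + len(right),
                                product_length=product,
                                strand=strand,
                            )
                        )
    return out


def design_primer_pairs(
    genome: Genome,
    contig_id: str,
    n_pairs: int,
    primer_len: int = 20,
    product_len: int = 400,
    max_product: int = 2000,
) -> list[PrimerPair]:
    """Cut primer pairs straight out of a template contig.

    The target contig is divided into n_pairs evenly spaced windows;
    in each, the forward primer is the window's first primer_len bases
    and the reverse primer is the reverse complement of the last
    primer_len bases of a product_len product. Useful for emulating an
    amplicon presence/absence panel on a synthetic genome.
    """
    contig = genome.contig(contig_id)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if product_len > len(contig) // n_pairs:
        raise ValueError("products do not fit the contig")
    pitch = len(contig) // n_pairs
    pairs = []
    for i in range(n_pairs):
        start = i * pitch
        template = contig.sequence[start : start + product_len]
        pairs.append(
            PrimerPair(
                name=f"{contig_id}_amp{i + 1}",
                forward=template[:primer_len],
                reverse=revcomp(template[-primer_len:]),
                max_product=max_product,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_replicon_tsv(statuses: Sequence[RepliconStatus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "replicon_class", "length", "mean_depth", "breadth", "classification"])
        for s in statuses:
            w.writerow([s.contig_id, s.replicon_class, s.length,
                        f"{s.mean_depth:.3f}", f"{s.breadth:.5f}", s.classification])


def write_amplicon_tsv(
    pairs: Sequence[PrimerPair],
    amplicons: Sequence[Amplicon],
    path: str | Path,
) -> None:
    """One row per primer pair: detected yes/no plus product coordinates."""
    by_name: dict[str, list[Amplicon]] = {}
    for a in amplicons:
        by_name.setdefault(a.name, []).append(a)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "detected", "contig", "start", "end", "length"])
        for pair in pairs:
            hits = by_name.get(pair.name, [])
            if not hits:
                w.writerow([pair.name, "no", ".", ".", ".", "."])
            for a in hits:
                w.writerow([a.name, "yes", a.contig_id, a.start, a.end, a.product_length])


def write_primers_tsv(pairs: Sequence[PrimerPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "forward", "reverse", "max_product"])
        for p in pairs:
            w.writerow([p.name, p.forward, p.reverse, p.max_product])


def read_primers_tsv(path: str | Path) -> list[PrimerPair]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                PrimerPair(
                    name=row["name"],
                    forward=row["forward"].upper(),
                    reverse=row["reverse"].upper(),
                    max_product=int(row["max_product"]),
                )
            )
    return out
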