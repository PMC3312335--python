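"""Codon-level annotation of SNP calls and WD-40 repeat scanning.

Variant positions are mapped into CDS coordinates (strand-aware, with
bases complemented for minus-strand genes), the affected codon is
translated before and after the substitution with the standard genetic
code, and the effect is labelled in the usual protein notation —
``P366S`` for a nonsynonymous change at codon 366, ``G190=`` for a
synonymous one.

The WD-40 scanner looks for the repeat signature described for this
motif family: an anchor dipeptide (VH, AH, SH or GH) followed, after a
conserved core of approximately 27 residues, by the terminal
tryptophan–aspartate (WD) dipeptide. The tolerated core length window
defaults to 24–31 residues around that approximate figure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import Seq

from ._dna import revcomp
from .pileup import VariantCall
from .synth import CdsFeature, Genome

__all__ = [
    "CdsHit",
    "CodonEffect",
    "Wd40Repeat",
    "locate_in_cds",
    "codon_effect",
    "annotate_calls",
    "scan_wd40",
    "translate_cds",
    "write_annotation_tsv",
    "write_wd40_tsv",
]

WD40_ANCHORS = ("VH", "AH", "SH", "GH")
DEFAULT_CORE_WINDOW = (24, 31)


@dataclass(frozen=True)
class CdsHit:
    """A variant located inside a CDS, in coding-strand coordinates."""

    locus_id: str
    cds_position: int  # 1-based within the CDS, 5' on the coding strand
    ref_base: str  # coding-strand bases
    alt_base: str
    feature: CdsFeature


@dataclass(frozen=True)
class CodonEffect:
    locus_id: str
    cds_position: int
    codon_index: int  # 1-based; ceil(cds_position / 3)
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool
    label: str  # e.g. "P366S", or "G190=" for synonymous


@dataclass(frozen=True)
class Wd40Repeat:
    start: int  # 1-based position of the anchor in the protein
    end: int  # 1-based position of the terminal D
    anchor: str
    core_length: int  # residues strictly between anchor and WD


def locate_in_cds(
    call: VariantCall,
    features: Sequence[CdsFeature],
    known_contigs: Optional[set[str]] = None,
) -> Optional[CdsHit]:
    """Map a variant into CDS coordinates, or None when intergenic.

    On the plus strand cds_position = pos - start + 1 with bases taken
    as-is; on the minus strand cds_position = end - pos + 1 with bases
    complemented. Features must be non-overlapping per strand; if a
    position falls in CDSs on both strands, the leftmost-starting
    feature wins (documented tie-break).
    """
    if known_contigs is not None and call.contig_id not in known_contigs:
        raise ValueError(f"variant on unknown contig {call.contig_id!r}")
    hits = [
        f
        for f in features
        if f.contig_id == call.contig_id and f.start <= call.position <= f.end
    ]
    if not hits:
        return None
    feat = min(hits, key=lambda f: f.start)
    if feat.strand == "+":
        cds_pos = call.position - feat.start + 1
        ref_b, alt_b = call.ref_base, call.alt_base
    else:
        cds_pos = feat.end - call.position + 1
        ref_b, alt_b = revcomp(call.ref_base), revcomp(call.alt_base)
    return CdsHit(
        locus_id=feat.locus_id,
        cds_position=cds_pos,
        ref_base=ref_b,
        alt_base=alt_b,
        feature=feat,
    )


def codon_effect(
    cds_sequence: str,
    cds_position: int,
    ref_base: str,
    alt_base: str,
    locus_id: str = "",
) -> CodonEffect:
    """Translate the affected codon before and after a substitution.

    cds_sequence is the coding-strand sequence (length divisible by 3);
    cds_position is 1-based within it and must carry ref_base. Internal
    codons are translated with the standard genetic code without
    start-codon special-casing.
    """
    if len(cds_sequence) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not (1 <= cds_position <= len(cds_sequence)):
        raise ValueError(f"cds_position {cds_position} outside CDS")
    if cds_sequence[cds_position - 1] != ref_base:
        raise ValueError(
            f"ref mismatch at CDS position {cds_position}: CDS has "
            f"{cds_sequence[cds_position - 1]}, call says {ref_base}"
        )
    codon_index = ceil(cds_position / 3)
    codon_start = (codon_index - 1) * 3
    ref_codon = cds_sequence[codon_start : codon_start + 3]
    offset = cds_position - 1 - codon_start
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    synonymous = ref_aa == alt_aa
    label = f"{ref_aa}{codon_index}=" if synonymous else f"{ref_aa}{codon_index}{alt_aa}"
    return CodonEffect(
        locus_id=locus_id,
        cds_position=cds_position,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=synonymous,
        label=label,
    )


@dataclass(frozen=True)
class AnnotatedCall:
    call: VariantCall
    hit: Optional[CdsHit]
    effect: Optional[CodonEffect]

    @property
    def label(self) -> str:
        return self.effect.label if self.effect else "intergenic"


def annotate_calls(
    calls: Sequence[VariantCall],
    genome: Genome,
) -> list[AnnotatedCall]:
    """Locate each call in the genome's CDS set and compute its effect."""
    contigs = {c.id for c in genome.contigs}
    out = []
    for call in calls:
        hit = locate_in_cds(call, genome.features, known_contigs=contigs)
        effect = None
        if hit is not None:
            cds_seq = genome.cds_sequence(hit.feature)
            effect = codon_effect(
                cds_seq, hit.cds_position, hit.ref_base, hit.alt_base,
                locus_id=hit.locus_id,
            )
        out.append(AnnotatedCall(call=call, hit=hit, effect=effect))
    return out


def translate_cds(cds_sequence: str) -> str:
    """Protein sequence of a CDS, trailing stop removed."""
    protein = str(Seq(cds_sequence).translate())
    return protein[:-1] if protein.endswith("*") else protein


def scan_wd40(
    protein: str,
    core_window: tuple[int, int] = DEFAULT_CORE_WINDOW,
) -> list[Wd40Repeat]:
    """Greedy left-to-right scan for WD-40 repeat units.

    A unit is an anchor dipeptide from {VH, AH, SH, GH} followed by a
    core of core_window residues and then the WD dipeptide. Matches are
    non-overlapping: after a unit is accepted, scanning resumes past
    its terminal D. When several core lengths fit one anchor, the
    shortest is taken.
    """
    lo, hi = core_window
    if not (0 <= lo <= hi):
        raise ValueError("invalid core window")
    out: list[Wd40Repeat] = []
    i = 0
    n = len(protein)
    while i < n - 1:
        if protein[i : i + 2] in WD40_ANCHORS:
            found = False
            for core in range(lo, hi + 1):
                j = i + 2 + core  # 0-based start of the WD dipeptide
                if j + 2 > n:
                    break
                if protein[j : j + 2] == "WD":
                    out.append(
                        Wd40Repeat(start=i + 1, end=j + 2, anchor=protein[i : i + 2],
                                   core_length=core)
                    )
                    i = j + 2
                    found = True
                    break
            if found:
                continue
        i += 1
    return out


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_annotation_tsv(annotated: Sequence[AnnotatedCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "pos", "ref", "alt", "locus", "cds_pos",
                    "codon_index", "ref_codon", "alt_codon", "effect", "synonymous"])
        for a in annotated:
            c = a.call
            if a.effect is None:
                w.writerow([c.contig_id, c.position, c.ref_base, c.alt_base,
                            ".", ".", ".", ".", ".", "intergenic", "."])
            else:
                e = a.effect
                w.writerow([c.contig_id, c.position, c.ref_base, c.alt_base,
                            e.locus_id, e.cds_position, e.codon_index,
                            e.ref_codon, e.alt_codon, e.label,
                            "yes" if e.synonymous else "no"])


def write_wd40_tsv(
    repeats_by_protein: dict[str, Sequence[Wd40Repeat]],
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein", "start", "end", "anchor", "core_length"])
        for pid, repeats in repeats_by_protein.items():
            for r in repeats:
                w.writerow([pid, r.start, r.end, r.anchor, r.core_length])
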