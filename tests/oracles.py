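"""Independent oracles: brute-force implementations used only by tests."""

from __future__ import annotations

from fractions import Fraction
from math import factorial

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def hamming_n(a: str, b: str) -> int:
    """Hamming distance where N mismatches everything."""
    return sum(x != y or x == "N" or y == "N" for x, y in zip(a, b))


def brute_force_align(read_seq: str, contigs: list[tuple[str, str]], max_mm: int):
    """All-placements scan over every contig, both strands.

    Returns (status, best_distance, placements) where placements are
    (contig_id, 1-based position, strand) at the minimum distance.
    Scanning per contig means junction placements cannot occur, matching
    the aligner's junction-rejection policy by construction.
    """
    length = len(read_seq)
    best = max_mm + 1
    hits: list[tuple[str, int, str]] = []
    for strand, seq in (("+", read_seq), ("-", rc(read_seq))):
        for cid, cseq in contigs:
            for i in range(len(cseq) - length + 1):
                d = hamming_n(cseq[i : i + length], seq)
                if d > max_mm:
                    continue
                if d < best:
                    best = d
                    hits = [(cid, i + 1, strand)]
                elif d == best:
                    hits.append((cid, i + 1, strand))
    if not hits:
        return "unaligned", None, []
    if len(hits) > 1:
        return "ambiguous", best, hits
    return "aligned", best, hits


# standard genetic code, written out independently of Biopython
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def table_probability(a: int, b: int, c: int, d: int) -> Fraction:
    """Hypergeometric probability of a 2x2 table from the factorial formula."""
    n = a + b + c + d
    num = (
        factorial(a + b) * factorial(c + d) * factorial(a + c) * factorial(b + d)
    )
    den = factorial(n) * factorial(a) * factorial(b) * factorial(c) * factorial(d)
    return Fraction(num, den)


def fisher_two_tailed_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by enumerating every table with the same margins."""
    r1, c1 = a + b, a + c
    n = a + b + c + d
    r2 = n - r1
    p_obs = table_probability(a, b, c, d)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_probability(x, r1 - x, c1 - x, r2 - (c1 - x))
        if p <= p_obs:
            total += p
    return float(total)
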