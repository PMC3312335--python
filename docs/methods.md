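# Methods

`alevar` re-creates, at desk scale, the computational side of a
wild-type-versus-evolved-strain resequencing comparison: detecting point
mutations and whole-replicon losses in a bacterial strain that changed during
adaptive laboratory evolution, annotating the protein-level consequences,
identifying an overproduced metabolite from exact masses, and testing the
association between exposure and outcome with an exact contingency test. This
note records the models, the parameter choices, and what the synthetic data
do and do not establish.

## Synthetic data model (`synth`)

The generator manufactures the inputs the analysis assumes rather than a
faithful Illumina simulation.

**Genome.** Ordered contigs, each classed `chromosome` or `plasmid`. The
default layout is a 200 kb chromosome plus a 50 kb dispensable plasmid —
a deliberate ~1/34 scale model of a *Streptomyces*-like genome (6.8 Mbp
chromosome + 1.8 Mbp megaplasmid) chosen so a full pipeline run takes
seconds, not hours; the chromosome:plasmid ratio is configurable, and the
21% genome-reduction figure is reproduced with the real sizes by metadata
arithmetic alone (`plasmid_fraction_percent`). Background sequence is i.i.d.
with GC fraction 0.72 (typical of streptomycetes). Ten CDSs of 900 bp are
spread over the contigs in proportion to length, at least 500 bp from contig
ends (so planted SNPs never sit in the low-coverage ramp at a contig edge),
strands random; every CDS is ATG + non-stop codons + stop on its own strand.

**Evolved genome.** A mutation list of SNPs (ref base checked against the
genome before substitution) and whole-replicon losses (plasmids only). The
default scenario plants 2 synonymous + 3 nonsynonymous coding SNPs on
replicons the evolved strain retains — a SNP on the dropped plasmid would be
unobservable by construction — plus the loss of the plasmid: six mutations,
mirroring the five-SNPs-plus-megaplasmid-loss structure of the motivating
experiment.

**Reads.** Single-end, fixed length (default 100 bp), origins uniform over
valid start positions per contig, strands uniform, read count
round(depth × contig length / read length) per contig at default depth 30×.
Errors are independent per-base substitutions to a uniformly random other
base at rate 0.005 (a round figure in the range of raw Illumina error rates).
No indels, no quality-dependent error structure, no paired ends — the
downstream aligner and caller are ungapped and substitution-only, so this is
the noise model the analysis is specified against. Every read records its
true origin, and the mutation list is written as a truth table, so recovery
is measurable without any real data.

What passing tests therefore show: the pipeline's logic is correct under its
own assumptions (unique sequence, uniform coverage, substitution noise).
What they do not show: robustness to repeats, indels, coverage bias, or
quality pathologies of real libraries.

## Alignment (`align`)

Contigs are concatenated into a single reference with an exact bijection
between global and per-contig coordinates, the way multi-contig draft
assemblies are commonly prepared for alignment. The aligner itself is a
deterministic, oracle-checkable stand-in for a production short-read mapper:
a k-mer seed index (k = 12) over the concatenation, with every
non-overlapping k-mer of the read used as a seed and each candidate placement
verified by full-read Hamming distance on either strand. By pigeonhole,
⌊L/k⌋ non-overlapping seeds guarantee that every placement with fewer than
⌊L/k⌋ mismatches is found — 8 mismatches' worth of guarantee for 100 bp
reads, above the highest mismatch budget used (5). When a read is too short
for that guarantee the aligner falls back to an exhaustive sliding-window
scan, so correctness never depends on read length.

The mismatch budget is escalated iteratively from 0 to 5, unaligned reads
feeding the next level. Because a read admitted at its first admitting level
has iteration level equal to its minimum Hamming distance, the iterative
scheme is computed in one pass per read; the equality `iteration_level ==
mismatch_count` is asserted in tests.

Placement policy (choices this package makes explicit):

- **Multi-best reads are discarded as ambiguous**, never placed randomly —
  this protects the count-ratio caller from repeat-induced false positives.
  Ties include a plus/minus tie at the same position. Ambiguous counts are
  logged.
- **Junction-spanning placements are rejected**: a window crossing the
  boundary of two concatenated contigs is not a real genomic locus.
- **N bases mismatch everything.**

## Pileup and variant calling (`pileup`)

The pileup is dense — every position of every contig has a column, so an
uncovered replicon is visible as a zero-depth stretch — with minus-strand
reads complemented back onto forward coordinates. Depth is the total column
count including N; N never contributes to reference or alternative counts.

A site is called polymorphic when the observed non-reference count strictly
exceeds `factor` × (reference base count), at total depth ≥ `min_depth`,
with defaults factor 2 and min_depth 10. "Observed count" is read as the
single most frequent non-reference base (`mode="top"`, the default); the
pooled non-reference sum is available as `mode="pooled"` since the
qualitative rule admits both readings. Strict inequality is used throughout;
a zero reference count with any alternative observations at sufficient depth
passes (alt > 2×0). Ties between the two top non-reference bases yield no
call. Both knobs are monotone: raising either can only remove calls
(property-tested).

## Replicon status and in-silico PCR (`replicon`)

Per replicon, mean depth and breadth (fraction of positions with depth ≥ 1)
are computed from the dense pileup. Classification is a pure function of
breadth: `absent` below 0.05, `present` at or above 0.90, `partial`
between. The thresholds are this package's operational definition of
"negligible coverage" — the phenomenon itself is qualitative — and are
configurable; `partial` exists to represent strains retaining only a portion
of a replicon.

In-silico PCR is exact-match: a product is reported when the forward primer
matches one strand and the reverse primer's reverse complement matches
exactly downstream on the same strand, primer sites non-overlapping, product
length ≤ the pair's maximum. Both orientations are searched, making the
operation strand-symmetric (property-tested). No mismatch tolerance,
degenerate bases, or thermodynamics: the emulated assay is presence/absence
of an amplicon panel, for which exact matching suffices on synthetic
genomes. `design_primer_pairs` cuts a panel directly from a template contig
for that purpose.

## Annotation (`annotate`)

Variants are mapped into CDS coordinates strand-aware (minus-strand genes:
position counted from the CDS 3′ genomic end, bases complemented). The
affected codon (`codon_index = ⌈cds_position/3⌉`) is translated before and
after substitution with the standard genetic code — for internal codons the
bacterial table 11 coincides with it, and start-codon special-casing is
deliberately not applied — and labelled `P366S`-style, with `=` for
synonymous changes. The synonymous flag is cross-checked in tests against an
independently written codon table.

The WD-40 scanner implements the classic repeat signature: an anchor
dipeptide (VH/AH/SH/GH) followed by a conserved core of approximately 27
residues and a terminal tryptophan–aspartate (WD) dipeptide. The tolerated
core window defaults to [24, 31] residues — the motif literature gives
"approximately 27" with no hard tolerance, so the window is configurable.
(Descriptions of the spacing sometimes say "base pairs" where residues are
clearly meant; residues are used here.) Scanning is left-to-right and
greedy: the shortest admissible core wins and matching resumes after the
terminal WD, so reported repeats are disjoint and ordered.

## Exact-mass identification (`massid`)

Monoisotopic masses are summed from a hard-coded table of standard atomic
masses (≥ 6 decimals; data, not logic). Cation m/z values subtract one
electron mass (5.4858 × 10⁻⁴ Da) — without this correction the fourth
decimal of high-resolution values is wrong. Supported adducts are [M+H]⁺
and [M+Na]⁺ (charge +1 only); neutral losses subtract an elementally
contained fragment formula. For holomycin the neutral composition
C₇H₆N₂O₂S₂ is used; published ion annotations sometimes print the
protonated composition (C₇H₇N₂O₂S₂) for both parent and fragment, which is
internally inconsistent with the printed masses, so all fragment masses here
are derived by subtraction from the neutral form. Matching reports
candidates within a ppm tolerance of an observed m/z, sorted by deviation.

## Fisher's exact test (`stats`)

Implemented from first principles with exact integer binomials and
`Fraction` arithmetic; the only floating-point step is the final conversion.
The two-sided convention is the small-p rule used by mainstream software:
sum the hypergeometric probabilities of all same-margin tables whose point
probability is ≤ that of the observed table, with a relative guard of 1e-12
on the comparison. Degenerate tables (an empty row or column) return p = 1.
The implementation is tested against a full-enumeration oracle (factorial
formula, all tables with the observed margins) and cross-checked against
scipy's independent implementation.

The two study tables are reconstructions from reported counts: 14 of 28
pathogen-exposed replicates versus 1 of 14 unexposed controls with enlarged
inhibition zones ([[14,14],[1,13]], p = 0.0071), and complete plasmid loss
in 2 of the 4 evolved strains with unambiguous PCR status versus 0 of 14
controls ([[2,2],[0,14]], p = 0.039); both reproduce the reported p-values
at the printed precision.

## Pipeline (`pipeline`) and problem sizes

`run_end_to_end` chains the stages deterministically from a single YAML-able
config; one structured log line per stage records input/output counts, and a
stage failure aborts with the stage name. A replicon loss is reported as one
catalog row, not per-base. The default run — 250 kb genome, 60,000 reads —
takes under ten seconds on one core; the acceptance-style recovery check
(ten seeds, default settings) runs in about 90 s. Test-suite simulations use
a 6 kb + 2 kb genome with 300 bp genes, which preserves every code path at a
fraction of the cost.

## Known limitations

- No indels anywhere: simulator, aligner, and caller are substitution-only.
- Ambiguous-read discarding makes repeated regions blind spots by design;
  distinguishing genuine segmental transfer from cross-mapping is out of
  scope.
- The breadth thresholds (0.05/0.90) are operational conventions, not
  estimates; real partial retentions near a threshold will be sensitive to
  them.
- Exact-match PCR ignores primer thermodynamics and near-matches.
- The caller reports no genotype likelihoods and uses no base qualities.
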