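# alevar

Resequencing analysis for adaptively evolved bacterial strains: SNP calling
by a count-ratio rule over iterative mismatch-escalation alignment,
whole-replicon-loss detection from coverage breadth with in-silico PCR
confirmation, codon-level effect annotation, exact-mass metabolite
identification, and exact contingency statistics — all runnable end to end
on a built-in synthetic-data generator with machine-readable ground truth.

## The problem

Adaptive laboratory evolution (ALE) selects mutants by serial passage under
a pressure — here, an antibiotic producer competed against a resistant
pathogen until it overproduces an inhibitory compound. Explaining the evolved
phenotype then requires comparing the evolved genome against its wild-type
ancestor from short-read resequencing data. The mutations of interest come in
two very different sizes: single-nucleotide substitutions inside genes, and
the wholesale loss of a dispensable megaplasmid that can carry a fifth of the
genome. `alevar` implements that comparison for users who want an auditable,
deterministic pipeline whose every stage is checkable against brute force,
plus the two side analyses such a study needs: identifying the overproduced
metabolite from high-resolution masses, and testing exposure/outcome
association across replicates.

## The method

- **Alignment.** Reference contigs are concatenated with exact global↔local
  coordinate maps. Reads are placed ungapped at minimum Hamming distance
  (k-mer seeds, k = 12, full-read verification, both strands); the allowed
  mismatch count is escalated 0 → 5, unaligned reads feeding the next level,
  so each read's iteration level equals its mismatch count. Multi-best reads
  are discarded as ambiguous; junction-spanning placements are rejected.
- **Calling.** A dense pileup (every position, zero-depth included) feeds
  the polymorphism rule: a site is variant when the top non-reference base
  count n_alt satisfies n_alt > 2·n_ref at total depth ≥ 10×.
- **Replicon loss.** Per replicon, breadth = fraction of positions with
  depth ≥ 1; breadth < 0.05 ⇒ absent, ≥ 0.90 ⇒ present, else partial.
  An exact-match in-silico PCR over primer panels confirms presence/absence.
- **Annotation.** Strand-aware CDS mapping, codon index ⌈p/3⌉, standard
  genetic code, labels like `P366S` / `G190=`; plus a WD-40 repeat scanner
  (anchor VH/AH/SH/GH, ~27-residue core, terminal WD).
- **Mass ID.** Monoisotopic m/z of [M+H]⁺/[M+Na]⁺ cations with electron-mass
  correction, neutral-loss fragments, ppm matching.
- **Statistics.** Exact two-tailed Fisher test (small-p convention) on 2×2
  tables, computed with exact rational arithmetic.

Model details, parameter defaults and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the default scenario — a 200 kb chromosome + 50 kb plasmid wild type;
an evolved strain with 5 coding SNPs and the plasmid lost; 30× coverage of
100 bp reads at 0.5% substitution error — and compare the calls against the
planted truth:

```console
$ alevar run --seed 7
6 mutations reported (recovered 6, missed 0, novel 0)
  replicon_loss pPLASMID:.        loss of replicon  planted
  snp           chromosome:1128   E91=              planted
  snp           chromosome:50501  R84H              planted
  snp           chromosome:100893 G298E             planted
  snp           chromosome:124996 Q41E              planted
  snp           chromosome:174962 R188=             planted
```

Each row is one entry of the mutation catalog: the plasmid is classified
absent from its coverage breadth (one catalog row, like a deletion event),
and every SNP is annotated with its gene and codon effect — `E91=` is a
synonymous change at codon 91, `R84H` an arginine→histidine substitution.
`planted` means the call matches the simulated truth exactly; `missed` and
`novel` rows would flag false negatives and false positives. Add
`--outdir DIR` to keep all artifacts (FASTA/FASTQ/SAM/VCF/TSV and the truth
table).

The side analyses from the same command-line tool:

```console
$ alevar fisher --table 14 14 1 13
p = 0.007147
$ alevar massid --formula C7H6N2O2S2 --adduct "[M+H]+" --loss C2H2O
[M+H]+ - C2H2O  172.9838
```

The first is the exact two-tailed Fisher p-value for 14/28 exposed
replicates versus 1/14 controls developing enlarged inhibition zones; the
second is the calculated m/z of the holothin fragment (ketene loss from
protonated holomycin). Every stage is also available as a library function
(`alevar.run_end_to_end`, `alevar.align_iterative`, `alevar.call_variants`,
`alevar.insilico_pcr`, `alevar.scan_wd40`, …) and as per-stage subcommands
(`simulate`, `align`, `call`, `replicon`, `pcr`, `annotate`, `wd40`,
`massmatch`).

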