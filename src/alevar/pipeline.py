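"""End-to-end orchestration: simulate -> align -> call -> classify -> annotate.

One run compares an "evolved" genome (planted SNPs plus a dropped
plasmid) against its wild-type ancestor exactly the way a resequencing
experiment would: reads are simulated from the evolved strain, aligned
to the wild-type reference with the escalating mismatch budget, piled
up, passed through the count-ratio caller and the replicon classifier,
annotated at codon level, and finally reconciled against the planted
truth to produce a mutation catalog with per-row provenance
(planted / missed / novel).

A run is fully determined by its RunConfig (serializable to YAML), so
two runs with the same config produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .align import align_iterative, build_reference, write_sam
from .annotate import AnnotatedCall, annotate_calls, write_annotation_tsv
from .pileup import VariantCall, call_variants, compute_pileup, write_pileup_tsv, write_vcf
from .replicon import (
    RepliconStatus,
    RepliconThresholds,
    replicon_summary,
    write_replicon_tsv,
)
from .synth import (
    ContigSpec,
    Genome,
    GenomeSpec,
    MutationSpec,
    apply_mutations,
    build_genome,
    design_snps,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_gff3,
    write_truth_tsv,
)

__all__ = [
    "RunConfig",
    "ReportRow",
    "TruthTally",
    "RunResult",
    "default_config",
    "run_end_to_end",
    "compare_to_truth",
    "plasmid_fraction_percent",
    "write_report_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything that determines a run.

    ``mutations`` may be given explicitly; when None, n_synonymous +
    n_nonsynonymous coding SNPs are designed from the wild-type genome
    and, with drop_plasmid, the first plasmid replicon is lost — the
    default evolved-strain scenario (5 SNPs + 1 replicon loss).
    """

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    mutations: Optional[list[MutationSpec]] = None
    n_synonymous: int = 2
    n_nonsynonymous: int = 3
    drop_plasmid: bool = True
    depth: float = 30.0
    read_len: int = 100
    err_rate: float = 0.005
    seed: int = 42
    min_depth: int = 10
    factor: float = 2.0
    call_mode: str = "top"
    max_level: int = 5
    seed_k: int = 12
    thresholds: RepliconThresholds = field(default_factory=RepliconThresholds)
    outdir: Optional[Path] = None

    # -- YAML round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "genome": {
                "contigs": [dataclasses.asdict(c) for c in self.genome.contigs],
                "gc": self.genome.gc,
                "n_cds": self.genome.n_cds,
                "cds_length": self.genome.cds_length,
                "cds_margin": self.genome.cds_margin,
                "seed": self.genome.seed,
            },
            "mutations": None
            if self.mutations is None
            else [dataclasses.asdict(m) for m in self.mutations],
            "n_synonymous": self.n_synonymous,
            "n_nonsynonymous": self.n_nonsynonymous,
            "drop_plasmid": self.drop_plasmid,
            "depth": self.depth,
            "read_len": self.read_len,
            "err_rate": self.err_rate,
            "seed": self.seed,
            "min_depth": self.min_depth,
            "factor": self.factor,
            "call_mode": self.call_mode,
            "max_level": self.max_level,
            "seed_k": self.seed_k,
            "thresholds": dataclasses.asdict(self.thresholds),
            "outdir": str(self.outdir) if self.outdir else None,
        }
        if self.genome.cds is not None:
            d["genome"]["cds"] = [list(t) for t in self.genome.cds]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        g = d.get("genome", {})
        genome = GenomeSpec(
            contigs=tuple(ContigSpec(**c) for c in g.get("contigs", GenomeSpec().contigs)),
            gc=g.get("gc", 0.72),
            n_cds=g.get("n_cds", 10),
            cds_length=g.get("cds_length", 900),
            cds_margin=g.get("cds_margin", 500),
            cds=tuple(tuple(t) for t in g["cds"]) if g.get("cds") else None,
            seed=g.get("seed", 0),
        )
        muts = d.get("mutations")
        mutations = None if muts is None else [MutationSpec(**m) for m in muts]
        thr = d.get("thresholds", {})
        return cls(
            genome=genome,
            mutations=mutations,
            n_synonymous=d.get("n_synonymous", 2),
            n_nonsynonymous=d.get("n_nonsynonymous", 3),
            drop_plasmid=d.get("drop_plasmid", True),
            depth=d.get("depth", 30.0),
            read_len=d.get("read_len", 100),
            err_rate=d.get("err_rate", 0.005),
            seed=d.get("seed", 42),
            min_depth=d.get("min_depth", 10),
            factor=d.get("factor", 2.0),
            call_mode=d.get("call_mode", "top"),
            max_level=d.get("max_level", 5),
            seed_k=d.get("seed_k", 12),
            thresholds=RepliconThresholds(**thr) if thr else RepliconThresholds(),
            outdir=Path(d["outdir"]) if d.get("outdir") else None,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 42, outdir: Optional[Path] = None) -> RunConfig:
    """The default evolved-vs-wild-type scenario at desk scale.

    200 kb chromosome + 50 kb plasmid, 10 CDSs, 2 synonymous + 3
    nonsynonymous coding SNPs, total plasmid dropout, 30x coverage of
    100 bp reads at 0.5% substitution error.
    """
    return RunConfig(genome=GenomeSpec(seed=seed), seed=seed, outdir=outdir)


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportRow:
    kind: str  # snp | replicon_loss
    contig_id: str
    position: Optional[int]
    ref_base: Optional[str]
    alt_base: Optional[str]
    locus_id: str
    effect: str
    truth_status: str  # planted | missed | novel


@dataclass(frozen=True)
class TruthTally:
    recovered: int
    missed: int
    novel: int

    @property
    def planted(self) -> int:
        return self.recovered + self.missed


def compare_to_truth(
    calls: Sequence[VariantCall],
    statuses: Sequence[RepliconStatus],
    truth: Sequence[MutationSpec],
) -> TruthTally:
    """Tally recovered / missed / novel mutations against the truth list.

    SNPs match on (contig, position, ref, alt) exactly; a replicon loss
    is recovered when the contig is classified absent. Contigs
    classified absent without a planted loss count as novel.
    """
    called_snps = {(c.contig_id, c.position, c.ref_base, c.alt_base) for c in calls}
    absent = {s.contig_id for s in statuses if s.classification == "absent"}
    truth_snps = {
        (m.contig_id, m.position, m.ref_base, m.alt_base)
        for m in truth
        if m.kind == "snp"
    }
    truth_losses = {m.contig_id for m in truth if m.kind == "replicon_loss"}
    recovered = len(called_snps & truth_snps) + len(absent & truth_losses)
    missed = len(truth_snps - called_snps) + len(truth_losses - absent)
    novel = len(called_snps - truth_snps) + len(absent - truth_losses)
    return TruthTally(recovered=recovered, missed=missed, novel=novel)


def _build_report(
    annotated: Sequence[AnnotatedCall],
    statuses: Sequence[RepliconStatus],
    truth: Sequence[MutationSpec],
) -> list[ReportRow]:
    rows: list[ReportRow] = []
    truth_losses = {m.contig_id for m in truth if m.kind == "replicon_loss"}
    absent = {s.contig_id for s in statuses if s.classification == "absent"}
    for cid in sorted(truth_losses | absent):
        status = (
            "planted" if cid in truth_losses and cid in absent
            else "missed" if cid in truth_losses
            else "novel"
        )
        rows.append(
            ReportRow(
                kind="replicon_loss", contig_id=cid, position=None,
                ref_base=None, alt_base=None, locus_id=".",
                effect="loss of replicon", truth_status=status,
            )
        )
    truth_snps = {
        (m.contig_id, m.position, m.ref_base, m.alt_base): m
        for m in truth
        if m.kind == "snp"
    }
    seen = set()
    for a in annotated:
        c = a.call
        key = (c.contig_id, c.position, c.ref_base, c.alt_base)
        seen.add(key)
        rows.append(
            ReportRow(
                kind="snp", contig_id=c.contig_id, position=c.position,
                ref_base=c.ref_base, alt_base=c.alt_base,
                locus_id=a.effect.locus_id if a.effect else ".",
                effect=a.label,
                truth_status="planted" if key in truth_snps else "novel",
            )
        )
    for key in sorted(set(truth_snps) - seen, key=lambda k: (k[0], k[1])):
        cid, pos, ref_b, alt_b = key
        rows.append(
            ReportRow(
                kind="snp", contig_id=cid, position=pos, ref_base=ref_b,
                alt_base=alt_b, locus_id=".", effect=".", truth_status="missed",
            )
        )
    rows.sort(key=lambda r: (r.kind != "replicon_loss", r.contig_id, r.position or 0))
    return rows


def plasmid_fraction_percent(genome: Genome | GenomeSpec) -> float:
    """Plasmid share of the genome, in percent (metadata arithmetic only).

    With the real replicon sizes (6.8 Mbp chromosome + 1.8 Mbp
    plasmid) this is the fraction of the genome removed by a total
    plasmid loss: 20.9%, i.e. 21% at integer precision.
    """
    if isinstance(genome, GenomeSpec):
        lengths = [(c.replicon_class, c.length) for c in genome.contigs]
    else:
        lengths = [(c.replicon_class, len(c)) for c in genome.contigs]
    total = sum(n for _, n in lengths)
    plasmid = sum(n for cls, n in lengths if cls == "plasmid")
    return 100.0 * plasmid / total


# ---------------------------------------------------------------------------
# The run itself
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: RunConfig
    wild: Genome
    evolved: Genome
    truth: list[MutationSpec]
    n_reads: int
    n_aligned: int
    n_ambiguous: int
    n_leftover: int
    calls: list[VariantCall]
    statuses: list[RepliconStatus]
    annotated: list[AnnotatedCall]
    report: list[ReportRow]
    tally: TruthTally


def run_end_to_end(config: RunConfig) -> RunResult:
    """Execute the whole pipeline on one config; write artifacts if outdir set."""
    stage = "build_genome"
    try:
        wild = build_genome(config.genome)
        logger.info("build_genome: %d contigs, %d CDS, %d bp",
                    len(wild.contigs), len(wild.features), wild.total_length)

        stage = "design_mutations"
        if config.mutations is not None:
            truth = list(config.mutations)
        else:
            # SNPs go on replicons the evolved strain retains: a SNP on a
            # dropped plasmid would be unobservable by construction.
            retained = None
            if config.drop_plasmid:
                plasmids = [c for c in wild.contigs if c.replicon_class == "plasmid"]
                if not plasmids:
                    raise ValueError("drop_plasmid requested but genome has no plasmid")
                retained = {c.id for c in wild.contigs if c.id != plasmids[0].id}
            truth = design_snps(
                wild, config.n_synonymous, config.n_nonsynonymous,
                seed=config.seed, contig_ids=retained,
            )
            if config.drop_plasmid:
                truth.append(MutationSpec(kind="replicon_loss", contig_id=plasmids[0].id))
        logger.info("design_mutations: %d planted", len(truth))

        stage = "apply_mutations"
        evolved = apply_mutations(wild, truth)

        stage = "simulate_reads"
        reads = simulate_reads(
            evolved, config.depth, config.read_len, config.err_rate, seed=config.seed
        )
        logger.info("simulate_reads: %d reads of %d bp", len(reads), config.read_len)

        stage = "align"
        ref = build_reference(wild.contigs)
        aln = align_iterative(reads, ref, max_level=config.max_level, k=config.seed_k)

        stage = "pileup"
        pile = compute_pileup(aln.alignments, ref)
        n_deep = int((pile.depth >= config.min_depth).sum())
        logger.info("pileup: %d columns at >= %dx", n_deep, config.min_depth)

        stage = "call_variants"
        calls = call_variants(
            pile, min_depth=config.min_depth, factor=config.factor, mode=config.call_mode
        )
        logger.info("call_variants: %d calls", len(calls))

        stage = "replicon_summary"
        statuses = replicon_summary(pile, wild, thresholds=config.thresholds)

        stage = "annotate"
        annotated = annotate_calls(calls, wild)

        stage = "report"
        tally = compare_to_truth(calls, statuses, truth)
        report = _build_report(annotated, statuses, truth)
        logger.info("report: %d rows (recovered %d, missed %d, novel %d)",
                    len(report), tally.recovered, tally.missed, tally.novel)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = RunResult(
        config=config, wild=wild, evolved=evolved, truth=truth,
        n_reads=len(reads), n_aligned=len(aln.alignments),
        n_ambiguous=len(aln.ambiguous), n_leftover=len(aln.leftovers),
        calls=calls, statuses=statuses, annotated=annotated,
        report=report, tally=tally,
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(wild, outdir / "ref.fasta")
        write_fasta(evolved, outdir / "evolved.fasta")
        write_gff3(wild, outdir / "features.gff3")
        write_fastq(reads, outdir / "reads.fastq")
        write_truth_tsv(truth, outdir / "truth.tsv")
        write_sam(aln, ref, outdir / "aln.sam")
        write_pileup_tsv(pile, outdir / "pile.tsv")
        write_vcf(calls, ref, outdir / "calls.vcf")
        write_replicon_tsv(statuses, outdir / "replicons.tsv")
        write_annotation_tsv(annotated, outdir / "annotated.tsv")
        write_report_tsv(report, outdir / "report.tsv")
        with open(outdir / "run.log", "w") as fh:
            fh.write(
                f"reads={result.n_reads}\taligned={result.n_aligned}\t"
                f"ambiguous={result.n_ambiguous}\tleftover={result.n_leftover}\n"
                f"calls={len(calls)}\trecovered={tally.recovered}\t"
                f"missed={tally.missed}\tnovel={tally.novel}\n"
            )
    return result


def write_report_tsv(report: Sequence[ReportRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tcontig\tposition\tref\talt\tlocus\teffect\ttruth_status\n")
        for r in report:
            fh.write(
                f"{r.kind}\t{r.contig_id}\t{r.position if r.position else '.'}\t"
                f"{r.ref_base or '.'}\t{r.alt_base or '.'}\t{r.locus_id}\t"
                f"{r.effect}\t{r.truth_status}\n"
            )
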