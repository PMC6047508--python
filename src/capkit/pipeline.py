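"""Stage orchestration: sample discovery, per-stage drivers, presets and
the one-command driver that runs assembly through allele alignment.

Read cleaning runs separately (its settings usually need per-dataset
iteration); ``automate_all`` picks up from a directory of cleaned FASTQ
files and produces contig MSAs and phased-allele MSAs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import assembly, cleaning, msa, phasing, refassembly, summary, targets
from .io import Read, SeqRecord, read_fasta, read_fastq, write_fasta, write_vcf

logger = logging.getLogger("capkit")


@dataclass(frozen=True)
class PresetProfile:
    name: str
    min_identity: float  # target-contig identity threshold
    max_edit_rate: float  # read-mapping edit-distance budget


PRESETS = {
    "relaxed": PresetProfile("relaxed", 0.75, 0.15),
    "medium": PresetProfile("medium", 0.85, 0.10),
    "conservative": PresetProfile("conservative", 0.95, 0.05),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def discover_samples(fastq_dir) -> dict[str, tuple[Path, Path]]:
    """Find samples by the ``<sample>_R1`` / ``<sample>_R2`` pattern."""
    fastq_dir = Path(fastq_dir)
    out: dict[str, tuple[Path, Path]] = {}
    for r1 in sorted(fastq_dir.glob("*_R1.fastq*")):
        sample = r1.name.split("_R1.fastq")[0]
        r2 = r1.with_name(r1.name.replace("_R1.fastq", "_R2.fastq"))
        if r2.exists():
            out[sample] = (r1, r2)
    if not out:
        raise FileNotFoundError(f"no <sample>_R1/_R2 FASTQ pairs found in {fastq_dir}")
    return out


def _log_stage(stage: str, config: dict) -> None:
    logger.info("stage %s: resolved config: %s", stage, config)


def clean_dataset(
    raw_dir, out_dir, cfg: cleaning.CleaningConfig, summary_path=None
) -> dict[str, cleaning.CleaningCounts]:
    """Run read cleaning for every sample in a directory."""
    _log_stage("clean-reads", asdict(cfg) | {"raw_dir": str(raw_dir)})
    out: dict[str, cleaning.CleaningCounts] = {}
    for sample, (r1, r2) in discover_samples(raw_dir).items():
        counts = cleaning.clean_sample(r1, r2, cfg, out_dir, sample)
        out[sample] = counts
        if summary_path:
            summary.update_summary(summary_path, sample, summary.COLUMNS[0], counts.raw_pairs)
            summary.update_summary(summary_path, sample, summary.COLUMNS[1], counts.cleaned_pairs)
        logger.info(
            "cleaned %s: %d raw pairs -> %d pairs + %d unpaired",
            sample, counts.raw_pairs, counts.cleaned_pairs, counts.unpaired,
        )
    return out


@dataclass
class PipelineResult:
    out_dir: Path
    samples: list[str]
    target_tables: list[targets.TargetContigTable] = field(default_factory=list)
    contig_msas: dict[str, msa.LocusAlignment] = field(default_factory=dict)
    allele_msas: dict[str, msa.LocusAlignment] = field(default_factory=dict)
    coverage: pd.DataFrame | None = None
    recovery: pd.DataFrame | None = None
    selected_loci: list[str] = field(default_factory=list)
    phased: dict[str, list[phasing.PhasedLocus]] = field(default_factory=dict)
    consensus_sequences: dict[str, dict[str, SeqRecord]] = field(default_factory=dict)


def _sample_reads(cleaned_dir: Path, sample: str) -> list[Read]:
    reads = list(read_fastq(cleaned_dir / f"{sample}_R1.fastq", "R1"))
    reads += list(read_fastq(cleaned_dir / f"{sample}_R2.fastq", "R2"))
    unpaired = cleaned_dir / f"{sample}_unpaired.fastq"
    if unpaired.exists():
        reads += list(read_fastq(unpaired, "unpaired"))
    return reads


def automate_all(
    cleaned_dir,
    reference_fasta,
    out_dir,
    preset: str = "medium",
    assembly_cfg: assembly.AssemblyConfig | None = None,
    min_samples: int = 3,
    keep_multilocus: bool = True,
    n_select: int | None = None,
    min_mean_depth: float = 0.0,
    force: bool = False,
) -> PipelineResult:
    """Run assembly -> target selection -> contig MSAs -> reference-based
    assembly (alignment-consensus reference) -> optional locus selection
    -> allele phasing -> allele MSAs. Any stage failure raises StageError
    naming the stage; prior outputs stay on disk."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    profile = PRESETS[preset]
    cleaned_dir = Path(cleaned_dir)
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"output directory {out_dir} is not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    assembly_cfg = assembly_cfg or assembly.AssemblyConfig()
    summary_path = out_dir / "summary_stats.txt"
    samples = sorted(discover_samples(cleaned_dir))
    result = PipelineResult(out_dir, samples)
    reference = list(read_fasta(reference_fasta))

    try:
        stage = "assemble-reads"
        t0 = time.time()
        _log_stage(stage, asdict(assembly_cfg))
        contig_dir = out_dir / "contigs"
        contig_dir.mkdir(exist_ok=True)
        contigs_by_sample: dict[str, list[assembly.Contig]] = {}
        for sample in samples:
            reads = _sample_reads(cleaned_dir, sample)
            contigs = assembly.assemble_sample(reads, assembly_cfg, sample)
            contigs_by_sample[sample] = contigs
            write_fasta(
                [SeqRecord(c.id, c.sequence) for c in contigs],
                contig_dir / f"{sample}_contigs.fasta",
            )
            summary.update_summary(summary_path, sample, summary.COLUMNS[2], len(contigs))
            logger.info("%s: %d contigs", sample, len(contigs))
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "find-target-contigs"
        t0 = time.time()
        _log_stage(stage, {"min_identity": profile.min_identity,
                           "keep_multilocus": keep_multilocus})
        target_dir = out_dir / "target_contigs"
        target_dir.mkdir(exist_ok=True)
        extracted_paths = []
        for sample in samples:
            table, extracted = targets.find_target_contigs(
                contigs_by_sample[sample], reference,
                min_identity=profile.min_identity,
                keep_multilocus=keep_multilocus,
            )
            result.target_tables.append(table)
            path = target_dir / f"{sample}_target_contigs.fasta"
            write_fasta([extracted[k] for k in sorted(extracted)], path)
            extracted_paths.append(path)
            # the summary column counts distinct matched contigs (a
            # multi-locus contig counts once, however many loci it serves)
            n_contigs = len(set(table.accepted.values()))
            summary.update_summary(summary_path, sample, summary.COLUMNS[3], n_contigs)
            logger.info("%s: %d target loci, %d paralog-excluded, %d multilocus contigs",
                        sample, len(table.accepted), len(table.excluded_paralog_loci),
                        len(table.multilocus_contigs))
        targets.write_flag_report(result.target_tables, target_dir / "flag_report.tsv")
        recovery, _counts = targets.recovery_matrix(result.target_tables, reference)
        result.recovery = recovery
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "align-sequences"
        t0 = time.time()
        _log_stage(stage, {"min_samples": min_samples})
        result.contig_msas = msa.build_locus_msas(extracted_paths, min_samples)
        msa.write_msas(result.contig_msas, out_dir / "msas")
        logger.info("stage %s done in %.1fs: %d MSAs", stage, time.time() - t0,
                    len(result.contig_msas))

        stage = "reference-assembly"
        t0 = time.time()
        _log_stage(stage, {"reference_type": "alignment-consensus",
                           "max_edit_rate": profile.max_edit_rate})
        asm_dir = out_dir / "assembly"
        asm_dir.mkdir(exist_ok=True)
        library = refassembly.build_reference("alignment-consensus", msas=result.contig_msas)[""]
        write_fasta([library.loci[k] for k in sorted(library.loci)],
                    asm_dir / "reference_library.fasta")
        pileups_by_sample: dict[str, dict[str, refassembly.LocusPileup]] = {}
        sites_by_sample: dict[str, list[refassembly.VariantSite]] = {}
        from .io import write_sam  # local import keeps module top tidy

        for sample in samples:
            reads = _sample_reads(cleaned_dir, sample)
            mapped = refassembly.map_reads(reads, library, profile.max_edit_rate)
            mapped = refassembly.mark_duplicates(mapped)
            write_sam(mapped, library.lengths(), asm_dir / f"{sample}.sam")
            pileups, sites = refassembly.pileup_and_variants(mapped, library)
            pileups_by_sample[sample] = pileups
            sites_by_sample[sample] = sites
            write_vcf(sites, asm_dir / f"{sample}.vcf")
            cons = {}
            for locus in sorted(pileups):
                rec = refassembly.assembly_consensus(pileups[locus], sites)
                if rec is not None:
                    cons[locus] = SeqRecord(f"{sample}_{locus}", rec.sequence)
            result.consensus_sequences[sample] = cons
            write_fasta([cons[k] for k in sorted(cons)], asm_dir / f"{sample}_consensus.fasta")
            on_target = sum(len(p.reads) for p in pileups.values())
            summary.update_summary(summary_path, sample, summary.COLUMNS[4], on_target)
            logger.info("%s: %d reads on target", sample, on_target)
        coverage, _mapped = refassembly.coverage_summary(pileups_by_sample)
        result.coverage = coverage
        coverage.round(3).to_csv(asm_dir / "coverage.tsv", sep="\t")
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        if n_select:
            stage = "locus-selection"
            _log_stage(stage, {"n": n_select, "min_mean_depth": min_mean_depth})
            result.selected_loci = refassembly.locus_selection(coverage, n_select, min_mean_depth)
            (out_dir / "selected_loci.txt").write_text(
                "".join(f"{locus}\n" for locus in result.selected_loci)
            )

        stage = "phase-alleles"
        t0 = time.time()
        _log_stage(stage, {})
        phased_dir = out_dir / "phased"
        allele_fastas = []
        for sample in samples:
            phased = phasing.phase_sample(
                pileups_by_sample[sample], sites_by_sample[sample], sample,
                phased_dir, library.lengths(),
            )
            result.phased[sample] = phased
            allele_fastas.append(phased_dir / f"{sample}_alleles.fasta")
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "align-alleles"
        t0 = time.time()
        _log_stage(stage, {"min_samples": min_samples})
        result.allele_msas = msa.build_locus_msas(allele_fastas, min_samples)
        msa.write_msas(result.allele_msas, out_dir / "allele_msas")
        logger.info("stage %s done in %.1fs: %d allele MSAs", stage, time.time() - t0,
                    len(result.allele_msas))

        summary.export_matrices(recovery, set(result.contig_msas), coverage, out_dir / "matrices")
    except Exception as exc:  # halt with the failing stage's name
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return result
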