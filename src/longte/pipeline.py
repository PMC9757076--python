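"""End-to-end orchestration: detect -> assemble/annotate -> quantify,
with per-stage outputs persisted under a run directory."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import assemble, detect, quantify
from .io import write_calls_bed, write_calls_json, write_calls_vcf, write_candidates_json
from .quantify import CNProfile, TECall
from .seqs import read_fasta, read_fastq, write_fasta
from .telib import TELibrary

log = logging.getLogger("longte.pipeline")


@dataclass
class PipelineConfig:
    """Paths and parameters of one run; defaults follow the method's
    stated values (20 bp overlap/gap thresholds, 1 kb read-extraction
    window, one polishing round)."""

    reads: str | Path = ""
    reference: str | Path = ""
    te_library: str | Path = ""
    bam: str | Path | None = None
    sniffles_vcf: str | Path | None = None
    cn_segments: str | Path | None = None
    outdir: str | Path = "longte_run"
    # detect
    min_sv_len: int = detect.DEFAULT_MIN_SV_LEN
    min_support: int = detect.DEFAULT_MIN_SUPPORT
    cluster_window: int = detect.DEFAULT_CLUSTER_WINDOW
    min_masked_frac: float = detect.DEFAULT_MIN_MASKED_FRAC
    # assemble / annotate
    overlap_threshold: int = assemble.DEFAULT_OVERLAP_THRESHOLD
    gap_threshold: int = assemble.DEFAULT_GAP_THRESHOLD
    polish_rounds: int = assemble.DEFAULT_POLISH_ROUNDS
    # quantify
    extract_window: int = quantify.DEFAULT_EXTRACT_WINDOW
    coverage_window: int = quantify.DEFAULT_COVERAGE_WINDOW
    default_ploidy: float = 2.0
    # misc
    seed: int = 0
    threads: int = 1

    def validate(self) -> None:
        for name in ("reads", "reference", "te_library"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing input {p!r}")
        for name in ("bam", "sniffles_vcf", "cn_segments"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing input {p!r}")
        for name in ("min_sv_len", "min_support", "cluster_window",
                     "overlap_threshold", "gap_threshold", "extract_window",
                     "coverage_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config.{name} must be positive")


@dataclass
class PipelineResult:
    calls: list[TECall]
    diagnostics: list[TECall]
    rejections: dict[str, int]
    outdir: Path

    @property
    def n_initial_candidates(self) -> int:
        return (
            len(self.calls)
            + len(self.diagnostics)
            + sum(self.rejections.values())
        )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    workdir = outdir / "work"
    workdir.mkdir(exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(
            {k: str(v) if isinstance(v, Path) else v
             for k, v in dataclasses.asdict(config).items()},
            indent=1,
        )
    )

    reference = read_fasta(config.reference)
    library = TELibrary.from_fasta(config.te_library)
    reads = read_fastq(config.reads)

    # stage 1: alignment + candidate detection + TE filtering
    if config.bam:
        bam = Path(config.bam)
    else:
        bam = detect.align_reads(config.reads, config.reference, workdir)
    if config.sniffles_vcf:
        candidates = detect.load_sniffles_vcf(config.sniffles_vcf)
    else:
        candidates = detect.call_insertions(
            bam,
            min_sv_len=config.min_sv_len,
            min_support=config.min_support,
            cluster_window=config.cluster_window,
        )
    write_candidates_json(candidates, outdir / "candidates.jsonl")
    te_candidates = detect.filter_te_candidates(
        candidates, library, min_masked_frac=config.min_masked_frac,
        workdir=workdir / "te_filter",
    )
    rejections: dict[str, int] = {
        "no_te_hit": len(candidates) - len(te_candidates)
    }
    log.info("%d insertion candidates, %d with TE library hits",
             len(candidates), len(te_candidates))

    cn_profile = (
        CNProfile.from_tsv(config.cn_segments) if config.cn_segments else None
    )

    calls: list[TECall] = []
    diagnostics: list[TECall] = []
    contig_records: list[tuple[str, str]] = []

    def reject(reason: str) -> None:
        rejections[reason] = rejections.get(reason, 0) + 1

    for cand in te_candidates:
        cand_dir = workdir / f"cand_{cand.id}"
        cand_dir.mkdir(exist_ok=True)
        support = assemble.collect_support_reads(
            cand, reads, bam_path=bam, window=config.extract_window
        )
        if not support:
            reject("no_support_reads")
            continue
        try:
            backbone = assemble.assemble_local_contig(
                support, cand, reference, workdir=cand_dir
            )
        except assemble.AssemblyError as exc:
            log.info("assembly failed: %s", exc)
            reject("assembly_failed")
            continue
        contig, rounds_done = assemble.polish_contig(
            backbone, support, rounds=config.polish_rounds, workdir=cand_dir
        )
        try:
            annotation = assemble.annotate_te_interval(contig, library,
                                                       workdir=cand_dir)
        except ValueError:
            reject("contig_too_short")
            continue
        if annotation is None:
            reject("no_te_on_contig")
            continue
        te_interval, family, strand = annotation
        asm = assemble.AssembledInsertion(
            candidate_id=cand.id,
            contig_sequence=contig,
            te_interval=te_interval,
            family=family,
            strand=strand,
            flank5_interval=(0, te_interval[0]),
            flank3_interval=(te_interval[1], len(contig)),
            polish_rounds=rounds_done,
        )
        contig_records.append(
            (f"{cand.id} family={family} strand={strand} "
             f"te={te_interval[0]}-{te_interval[1]}", contig)
        )
        fm5, fm3 = assemble.map_flanks(asm.flank5, asm.flank3,
                                       config.reference, workdir=cand_dir)
        try:
            resolution = assemble.resolve_breakpoint(
                fm5, fm3,
                overlap_threshold=config.overlap_threshold,
                gap_threshold=config.gap_threshold,
                reference=reference,
            )
        except ValueError as exc:
            log.info("breakpoint rejected for %s: %s", cand.id, exc)
            reject("inconsistent_flanks")
            continue

        flags: set[str] = set()
        if cand.nested:
            flags.add("nested")
        if (fm5 and fm5.ambiguous) or (fm3 and fm3.ambiguous):
            flags.add("ambiguous_flank")

        call = TECall(
            id=cand.id,
            contig=resolution.contig or cand.contig,
            start=resolution.start,
            end=resolution.end,
            family=family,
            strand=strand,
            tsd_sequence=resolution.tsd_sequence,
            tsd_length=resolution.tsd_length,
            status=resolution.status,
            te_sequence=asm.te_sequence,
            support_count=cand.support_count,
            flags=flags,
        )
        if resolution.status != assemble.STATUS_RESOLVED:
            diagnostics.append(call)
            continue

        nearby = quantify.extract_nearby_reads(
            bam, call.contig, call.start, call.end, window=config.extract_window
        )
        junction = quantify.junction_coverages(
            nearby, contig, te_interval,
            window_bp=config.coverage_window, workdir=cand_dir,
        )
        taf = quantify.estimate_taf(junction)
        cn_value, cn_flags = quantify.local_copy_number(
            cn_profile, call.contig, call.start, call.end,
            default_ploidy=config.default_ploidy,
        )
        call.junction = junction
        call.raw_taf = taf.raw_taf
        call.taf = taf.taf
        call.local_cn = cn_value
        call.flags |= junction.flags | taf.flags | cn_flags
        if taf.raw_taf is not None:
            call.allele_copy_number = quantify.allele_copy_number(
                taf.raw_taf, cn_value
            )
        calls.append(call)

    calls = _dedupe(calls, window=config.cluster_window)

    write_fasta(outdir / "contigs.fasta", contig_records)
    write_calls_json(calls, outdir / "calls.jsonl")
    write_calls_bed(calls, outdir / "calls.bed")
    write_calls_vcf(calls, outdir / "calls.vcf", reference)
    write_calls_json(diagnostics, outdir / "diagnostics.jsonl")
    (outdir / "rejections.json").write_text(json.dumps(rejections, indent=1))
    if not calls:
        log.warning("empty final call set")
    return PipelineResult(calls=calls, diagnostics=diagnostics,
                          rejections=rejections, outdir=outdir)


def _dedupe(calls: list[TECall], window: int) -> list[TECall]:
    """Collapse calls of the same family within ``window`` bp, keeping
    the best-supported one."""
    calls = sorted(calls, key=lambda c: (c.contig, c.family, c.start))
    out: list[TECall] = []
    for call in calls:
        prev = out[-1] if out else None
        if (
            prev
            and prev.contig == call.contig
            and prev.family == call.family
            and abs(prev.start - call.start) <= window
        ):
            if call.support_count > prev.support_count:
                out[-1] = call
            continue
        out.append(call)
    out.sort(key=lambda c: (c.contig, c.start))
    return out
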