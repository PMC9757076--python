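"""Stage 1: insertion SV candidates from long-read alignments, filtered
to TE-insertion candidates against the TE library.

Candidates are kept only when (i) the variant is an insertion, (ii) the
inserted sequence is recoverable, and (iii) the inserted sequence has
hits to the curated TE library.
"""

from __future__ import annotations

import logging
import statistics
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .align import merged_span, paf_records, run_minimap2, sort_and_index
from .telib import TELibrary

log = logging.getLogger("longte.detect")

DEFAULT_MIN_SV_LEN = 100
DEFAULT_MIN_SUPPORT = 5
DEFAULT_CLUSTER_WINDOW = 100
DEFAULT_MIN_CLIP = 500
DEFAULT_MIN_MASKED_FRAC = 0.1


@dataclass
class InsertionCandidate:
    """A clustered insertion signal on the reference."""

    id: str
    contig: str
    position: int  # 0-based breakpoint estimate
    insert_sequence: str
    support_read_ids: set[str]
    needs_read_recollection: bool = False

    @property
    def support_count(self) -> int:
        return len(self.support_read_ids)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "contig": self.contig,
            "position": self.position,
            "insert_length": len(self.insert_sequence),
            "support_count": self.support_count,
            "support_read_ids": sorted(self.support_read_ids),
        }


@dataclass
class TECandidate(InsertionCandidate):
    family_hits: list[tuple[str, int, float]] = field(default_factory=list)
    dominant_family: str = ""
    nested: bool = False


@dataclass(frozen=True)
class Signature:
    """One per-read insertion signal: a large CIGAR I op, a split-read
    pair with a query gap, or a long soft clip at a breakpoint."""

    read: str
    contig: str
    position: int
    length: int
    sequence: str | None
    kind: str  # "cigar" | "split" | "clip"


def align_reads(
    reads_fastq: Path | str,
    reference_fasta: Path | str,
    workdir: Path | str,
    preset: str = "map-pb",
) -> Path:
    """Align long reads to the reference; returns a sorted, indexed BAM."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    sam = run_minimap2(reference_fasta, reads_fastq, workdir / "reads.sam",
                       preset=preset, sam=True)
    bam = sort_and_index(sam, workdir / "reads.bam")
    sam.unlink()
    with pysam.AlignmentFile(str(bam)) as fh:
        if fh.mapped == 0:
            log.warning("no reads aligned to %s", reference_fasta)
    return bam


def _record_segments(recs: list[pysam.AlignedSegment]):
    """Alignment segments per (contig, strand), query coords in the
    stored orientation (consistent among same-strand records of a read)."""
    segs = []
    for rec in recs:
        segs.append(
            (
                rec.reference_name,
                "-" if rec.is_reverse else "+",
                rec.query_alignment_start,
                rec.query_alignment_end,
                rec.reference_start,
                rec.reference_end,
                rec,
            )
        )
    return segs


def collect_signatures(
    bam_path: Path | str,
    min_sv_len: int = DEFAULT_MIN_SV_LEN,
    min_clip: int = DEFAULT_MIN_CLIP,
    region: tuple[str, int, int] | None = None,
) -> list[Signature]:
    sigs: list[Signature] = []
    by_read: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as fh:
        it = fh.fetch(*region) if region else fh
        for rec in it:
            if rec.is_unmapped or rec.is_secondary:
                continue
            by_read[rec.query_name].append(rec)

    for read, recs in by_read.items():
        seq_bearing = False
        # large insertion ops within a single alignment
        for rec in recs:
            refpos = rec.reference_start
            qpos = 0
            q = rec.query_sequence
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    refpos += ln
                    qpos += ln
                elif op == 1:  # I
                    if ln >= min_sv_len:
                        seq = q[qpos : qpos + ln] if q else None
                        sigs.append(
                            Signature(read, rec.reference_name, refpos, ln, seq, "cigar")
                        )
                        seq_bearing = True
                    qpos += ln
                elif op == 2:  # D
                    refpos += ln
                elif op == 3:  # N
                    refpos += ln
                elif op == 4:  # S
                    qpos += ln
        # split-read pairs: adjacent on the reference, gapped on the query
        groups: dict[tuple[str, str], list] = defaultdict(list)
        for seg in _record_segments(recs):
            groups[(seg[0], seg[1])].append(seg)
        for (contig, _strand), segs in groups.items():
            segs.sort(key=lambda s: s[2])
            for a, b in zip(segs, segs[1:]):
                qgap = b[2] - a[3]
                rgap = b[4] - a[5]
                ins_len = qgap - max(rgap, 0)
                if ins_len >= min_sv_len and abs(rgap) <= min_sv_len:
                    seq = None
                    for rec in (a[6], b[6]):
                        if rec.query_sequence:
                            seq = rec.query_sequence[a[3] : b[2]]
                            break
                    sigs.append(
                        Signature(read, contig, a[5], ins_len, seq, "split")
                    )
                    seq_bearing = True
        # long soft clips, only for reads without a sequence-level signal
        if not seq_bearing:
            for rec in recs:
                ct = rec.cigartuples
                if ct[0][0] == 4 and ct[0][1] >= min_clip:
                    sigs.append(
                        Signature(read, rec.reference_name, rec.reference_start,
                                  ct[0][1], None, "clip")
                    )
                if ct[-1][0] == 4 and ct[-1][1] >= min_clip:
                    sigs.append(
                        Signature(read, rec.reference_name, rec.reference_end,
                                  ct[-1][1], None, "clip")
                    )
    return sigs


def call_insertions(
    bam_path: Path | str,
    min_sv_len: int = DEFAULT_MIN_SV_LEN,
    min_support: int = DEFAULT_MIN_SUPPORT,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_clip: int = DEFAULT_MIN_CLIP,
) -> list[InsertionCandidate]:
    """Cluster per-read insertion signatures into insertion candidates.

    Signatures within ``cluster_window`` of one another (single linkage)
    form a cluster; clusters supported by >= ``min_support`` distinct
    reads and carrying at least one recoverable inserted sequence emit a
    candidate at the median signature position, with the inserted
    sequence taken from the read with the longest inserted segment.
    """
    sigs = collect_signatures(bam_path, min_sv_len=min_sv_len, min_clip=min_clip)
    by_contig: dict[str, list[Signature]] = defaultdict(list)
    for s in sigs:
        by_contig[s.contig].append(s)

    candidates: list[InsertionCandidate] = []
    for contig in sorted(by_contig):
        cluster: list[Signature] = []
        contig_sigs = sorted(by_contig[contig], key=lambda s: s.position)

        def flush(cluster: list[Signature]) -> None:
            reads = {s.read for s in cluster}
            if len(reads) < min_support:
                return
            with_seq = [s for s in cluster if s.sequence]
            if not with_seq:
                return  # inserted sequence unavailable
            pos = int(statistics.median(s.position for s in cluster))
            best = max(with_seq, key=lambda s: s.length)
            candidates.append(
                InsertionCandidate(
                    id=f"{contig}_{pos}",
                    contig=contig,
                    position=pos,
                    insert_sequence=best.sequence,
                    support_read_ids=reads,
                )
            )

        for s in contig_sigs:
            if cluster and s.position - cluster[-1].position > cluster_window:
                flush(cluster)
                cluster = []
            cluster.append(s)
        if cluster:
            flush(cluster)
    candidates.sort(key=lambda c: (c.contig, c.position))
    return candidates


def load_sniffles_vcf(vcf_path: Path | str) -> list[InsertionCandidate]:
    """Ingest Sniffles-dialect SV calls, keeping SVTYPE=INS records with a
    resolvable inserted sequence (ALT or INFO SEQ).  Missing RNAMES keeps
    the candidate with an empty read set and a re-collection flag."""
    kept: list[InsertionCandidate] = []
    dropped = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype != "INS":
                dropped += 1
                continue
            seq = None
            alt = rec.alts[0] if rec.alts else None
            if alt and not alt.startswith("<"):
                seq = alt
                if rec.ref and seq.startswith(rec.ref):
                    seq = seq[len(rec.ref):]
            if not seq:
                info_seq = rec.info.get("SEQ")
                if info_seq and info_seq not in (".",):
                    seq = str(info_seq)
            if not seq:
                dropped += 1
                continue
            rnames = rec.info.get("RNAMES", ())
            if isinstance(rnames, str):
                rnames = rnames.split(",")
            reads = {r for r in rnames if r}
            kept.append(
                InsertionCandidate(
                    id=f"{rec.contig}_{rec.start}",
                    contig=rec.contig,
                    position=rec.start,
                    insert_sequence=seq.upper(),
                    support_read_ids=reads,
                    needs_read_recollection=not reads,
                )
            )
    if dropped:
        log.info("dropped %d VCF records (not INS or sequence unavailable)", dropped)
    return kept


def filter_te_candidates(
    candidates: list[InsertionCandidate],
    te_library: TELibrary,
    min_masked_frac: float = DEFAULT_MIN_MASKED_FRAC,
    workdir: Path | str | None = None,
) -> list[TECandidate]:
    """Keep candidates whose inserted sequence is masked by the TE
    library over >= ``min_masked_frac`` of its length (both strands);
    the dominant family is the one with the largest masked span, and a
    second family over the threshold sets the ``nested`` flag."""
    if not candidates:
        return []
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        from .seqs import write_fasta

        ins_fa = write_fasta(
            wd / "inserts.fa",
            ((c.id, c.insert_sequence) for c in candidates),
        )
        # one pass per family: keeps short nested hits that would be
        # suppressed as secondaries of a dominant family's chain
        per_query: dict[str, dict[str, list]] = defaultdict(lambda: defaultdict(list))
        for fam in te_library:
            fam_fa = write_fasta(wd / "family.fa", [(fam.name, fam.sequence)])
            paf = run_minimap2(fam_fa, ins_fa, wd / "inserts_vs_family.paf",
                               preset="map-pb", sam=False, base_level=True,
                               secondary=True)
            for hit in paf_records(paf):
                per_query[hit.query][hit.target].append(hit)

        out: list[TECandidate] = []
        for cand in candidates:
            fams = per_query.get(cand.id, {})
            if not fams:
                continue
            hits = []
            all_intervals = []
            for fam, fam_hits in fams.items():
                ivals = [(h.query_start, h.query_end) for h in fam_hits]
                span = merged_span(ivals)
                aln = sum(h.alignment_length for h in fam_hits)
                matches = sum(h.matches for h in fam_hits)
                hits.append((fam, span, matches / aln if aln else 0.0))
                all_intervals.extend(ivals)
            hits.sort(key=lambda x: -x[1])
            total_frac = merged_span(all_intervals) / len(cand.insert_sequence)
            if total_frac < min_masked_frac:
                continue
            thresh = min_masked_frac * len(cand.insert_sequence)
            nested = sum(1 for _, span, _ in hits if span >= thresh) > 1
            out.append(
                TECandidate(
                    id=cand.id,
                    contig=cand.contig,
                    position=cand.position,
                    insert_sequence=cand.insert_sequence,
                    support_read_ids=set(cand.support_read_ids),
                    needs_read_recollection=cand.needs_read_recollection,
                    family_hits=hits,
                    dominant_family=hits[0][0],
                    nested=nested,
                )
            )
        return out
    finally:
        if ctx:
            ctx.cleanup()
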