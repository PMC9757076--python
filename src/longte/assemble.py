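"""Stages 2-3: local assembly and polishing of each candidate, TE
interval annotation on the contig, flank re-mapping, and breakpoint/TSD
resolution on reference coordinates.

The built-in assembler is backbone+consensus: the best insertion-
spanning support read becomes the contig backbone, then one or more
rounds of read alignment and column-wise majority consensus (including
indels) polish it.  This is deterministic and adequate at local scale.
"""

from __future__ import annotations

import logging
import tempfile
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .align import paf_records, run_minimap2, sam_records
from .detect import InsertionCandidate, collect_signatures
from .seqs import revcomp, to_codes, write_fasta
from .telib import TELibrary

log = logging.getLogger("longte.assemble")

DEFAULT_OVERLAP_THRESHOLD = 20
DEFAULT_GAP_THRESHOLD = 20
DEFAULT_POLISH_ROUNDS = 1
DEFAULT_MIN_FLANK = 500
MIN_FLANK_FOR_MAPPING = 100
AMBIGUITY_MARGIN = 0.05

STATUS_RESOLVED = "resolved"
STATUS_GAP_EXCEEDED = "gap_exceeded"
STATUS_OVERLAP_EXCEEDED = "overlap_exceeded"
STATUS_ONE_FLANK_ONLY = "one_flank_only"


@dataclass
class AssembledInsertion:
    candidate_id: str
    contig_sequence: str
    te_interval: tuple[int, int]  # 0-based half-open, contig coords
    family: str
    strand: str
    flank5_interval: tuple[int, int]
    flank3_interval: tuple[int, int]
    polish_rounds: int

    @property
    def flank5(self) -> str:
        return self.contig_sequence[self.flank5_interval[0] : self.flank5_interval[1]]

    @property
    def flank3(self) -> str:
        return self.contig_sequence[self.flank3_interval[0] : self.flank3_interval[1]]

    @property
    def te_sequence(self) -> str:
        return self.contig_sequence[self.te_interval[0] : self.te_interval[1]]


@dataclass
class FlankMapping:
    """Best unique reference placement of one contig flank."""

    contig: str
    start: int
    end: int
    strand: str
    query_length: int
    query_start: int
    query_end: int
    ambiguous: bool = False


@dataclass
class BreakpointResolution:
    contig: str | None
    start: int
    end: int
    tsd_sequence: str | None
    tsd_length: int
    status: str


class AssemblyError(RuntimeError):
    pass


def collect_support_reads(
    candidate: InsertionCandidate,
    reads: Mapping[str, str],
    bam_path: Path | str | None = None,
    window: int = 1000,
) -> dict[str, str]:
    """Fetch the sequences of the candidate's supporting reads.

    With named supporting reads, returns exactly those (warning on
    absentees).  With an empty read set (VCF ingest without RNAMES), the
    reads are re-collected from the alignment file: any read with an
    insertion or clip signature within ``window`` of the candidate
    position.
    """
    if candidate.support_read_ids:
        out = {}
        missing = 0
        for name in candidate.support_read_ids:
            if name in reads:
                out[name] = reads[name]
            else:
                missing += 1
        if missing:
            log.warning("%s: %d supporting reads absent from read set",
                        candidate.id, missing)
        return out
    if bam_path is None:
        return {}
    sigs = collect_signatures(
        bam_path,
        region=(candidate.contig, max(0, candidate.position - window),
                candidate.position + window),
    )
    names = {
        s.read for s in sigs if abs(s.position - candidate.position) <= window
    }
    return {n: reads[n] for n in names if n in reads}


def _read_signature_anchors(
    support_reads: Mapping[str, str],
    candidate: InsertionCandidate,
    reference: Mapping[str, str],
    workdir: Path,
    min_sv_len: int = 100,
    region_pad: int = 30_000,
) -> dict[str, tuple[int, int]]:
    """For each support read with an insertion signature near the
    candidate, the (left, right) reference anchor extents around it."""
    ref_seq = reference[candidate.contig]
    lo = max(0, candidate.position - region_pad)
    hi = min(len(ref_seq), candidate.position + region_pad)
    ref_fa = write_fasta(workdir / "region.fa", [("region", ref_seq[lo:hi])])
    reads_fa = write_fasta(workdir / "support.fa", support_reads.items())
    sam = run_minimap2(ref_fa, reads_fa, workdir / "support_vs_region.sam",
                       preset="map-pb", sam=True)
    bam = workdir / "support_vs_region.bam"
    import pysam

    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    target = candidate.position - lo
    anchors: dict[str, tuple[int, int]] = {}

    def offer(read: str, left: int, right: int) -> None:
        prev = anchors.get(read)
        if prev is None or min(left, right) > min(prev):
            anchors[read] = (left, right)

    by_read: dict[str, list] = {}
    for rec in sam_records(bam):
        by_read.setdefault(rec.query_name, []).append(rec)
    for read, recs in by_read.items():
        # aligned extents on each side of an insertion signature
        for rec in recs:
            refpos = rec.reference_start
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8, 2, 3):
                    refpos += ln
                elif op == 1 and ln >= min_sv_len and abs(refpos - target) <= 1000:
                    offer(read, refpos - rec.reference_start,
                          rec.reference_end - refpos)
        segs = sorted(
            ((r.query_alignment_start, r.query_alignment_end,
              r.reference_start, r.reference_end) for r in recs
             if ("-" if r.is_reverse else "+") ==
                ("-" if recs[0].is_reverse else "+")),
        )
        for a, b in zip(segs, segs[1:]):
            qgap = b[0] - a[1]
            rgap = b[2] - a[3]
            if qgap - max(rgap, 0) >= min_sv_len and abs(rgap) <= min_sv_len \
                    and abs(a[3] - target) <= 1000:
                offer(read, a[3] - a[2], b[3] - b[2])
    return anchors


def assemble_local_contig(
    support_reads: Mapping[str, str],
    candidate: InsertionCandidate,
    reference: Mapping[str, str],
    workdir: Path | str | None = None,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> str:
    """Pick the insertion-spanning support read with the widest anchors
    as the contig backbone (reference-forward orientation).  Raises
    :class:`AssemblyError` when no read spans the insertion with at
    least ``MIN_FLANK_FOR_MAPPING`` bp of anchor on both sides."""
    if len(support_reads) < 2:
        raise AssemblyError(f"{candidate.id}: need >= 2 supporting reads")
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        anchors = _read_signature_anchors(support_reads, candidate, reference, wd)
        if not anchors:
            raise AssemblyError(f"{candidate.id}: no spanning support read")
        # prefer reads with >= min_flank anchors on both sides
        def key(name: str):
            left, right = anchors[name]
            return (min(left, right) >= min_flank, min(left, right))

        best = max(anchors, key=key)
        left, right = anchors[best]
        if min(left, right) < MIN_FLANK_FOR_MAPPING:
            raise AssemblyError(f"{candidate.id}: spanning anchors too short")
        # backbone in reference-forward orientation
        seq = support_reads[best]
        for rec in sam_records(_last_support_sam(wd)):
            if rec.query_name == best:
                if rec.is_reverse:
                    seq = revcomp(seq)
                break
        return seq
    finally:
        if ctx:
            ctx.cleanup()


def _last_support_sam(wd: Path) -> Path:
    return wd / "support_vs_region.sam"


def polish_contig(
    contig: str,
    support_reads: Mapping[str, str],
    rounds: int = DEFAULT_POLISH_ROUNDS,
    workdir: Path | str | None = None,
) -> tuple[str, int]:
    """Iteratively align supporting reads to the contig and take a
    column-wise majority consensus (ties keep the current base;
    consistent insertions/deletions in the read pile are applied).
    ``rounds=0`` returns the input unchanged."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    done = 0
    for _ in range(rounds):
        contig = _consensus_round(contig, support_reads, workdir)
        done += 1
    return contig, done


def _consensus_round(
    contig: str, support_reads: Mapping[str, str], workdir: Path | str | None
) -> str:
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        contig_fa = write_fasta(wd / "contig.fa", [("contig", contig)])
        reads_fa = write_fasta(wd / "polish_reads.fa", support_reads.items())
        sam = run_minimap2(contig_fa, reads_fa, wd / "polish.sam",
                           preset="map-pb", sam=True)
        L = len(contig)
        counts = np.zeros((5, L), dtype=np.int32)  # A C G T deletion
        insertions: dict[int, Counter] = defaultdict(Counter)
        for rec in sam_records(sam):
            q = rec.query_sequence
            if not q:
                continue
            qcodes = to_codes(q.upper().replace("N", "A"))
            rp = rec.reference_start
            qp = 0
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):
                    np.add.at(counts, (qcodes[qp : qp + ln], np.arange(rp, rp + ln)), 1)
                    rp += ln
                    qp += ln
                elif op == 1:
                    insertions[rp][q[qp : qp + ln]] += 1
                    qp += ln
                elif op == 2:
                    counts[4, rp : rp + ln] += 1
                    rp += ln
                elif op == 3:
                    rp += ln
                elif op == 4:
                    qp += ln
        depth = counts.sum(axis=0)
        cur_codes = to_codes(contig)
        bases = "ACGT"
        out: list[str] = []
        for i in range(L):
            ins = insertions.get(i)
            if ins:
                seq, cnt = ins.most_common(1)[0]
                local_depth = depth[i] if depth[i] > 0 else (depth[i - 1] if i else 0)
                if cnt * 2 > local_depth:
                    out.append(seq)
            if depth[i] == 0:
                out.append(contig[i])
                continue
            col = counts[:, i]
            m = int(col.max())
            cur = int(cur_codes[i])
            if col[cur] == m:
                winner = cur  # tie (or current majority) keeps current base
            else:
                winner = int(col.argmax())
            if winner != 4:
                out.append(bases[winner])
        ins = insertions.get(L)
        if ins:
            seq, cnt = ins.most_common(1)[0]
            if L and cnt * 2 > depth[L - 1]:
                out.append(seq)
        return "".join(out)
    finally:
        if ctx:
            ctx.cleanup()


def annotate_te_interval(
    contig: str,
    te_library: TELibrary,
    workdir: Path | str | None = None,
    min_contig: int = 1000,
) -> tuple[tuple[int, int], str, str] | None:
    """Locate the TE on the contig by aligning the library against it.

    Returns (te_interval, family, strand) for the dominant family (the
    library entry with the largest masked span on the contig), or
    ``None`` when no library entry hits the contig.
    """
    if len(contig) < min_contig:
        raise ValueError(f"contig too short to annotate ({len(contig)} bp)")
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        contig_fa = write_fasta(wd / "annot_contig.fa", [("contig", contig)])
        lib_fa = te_library.to_fasta(wd / "annot_lib.fa")
        paf = run_minimap2(contig_fa, lib_fa, wd / "lib_vs_contig.paf",
                           preset="map-pb", sam=False, base_level=True)
        by_family: dict[str, list] = defaultdict(list)
        for hit in paf_records(paf):
            by_family[hit.query].append(hit)
        if not by_family:
            return None
        spans = {
            fam: sum(h.target_end - h.target_start for h in hits)
            for fam, hits in by_family.items()
        }
        family = max(spans, key=spans.get)
        hits = by_family[family]
        start = min(h.target_start for h in hits)
        end = max(h.target_end for h in hits)
        longest = max(hits, key=lambda h: h.target_end - h.target_start)
        return (start, end), family, longest.strand
    finally:
        if ctx:
            ctx.cleanup()


def map_flanks(
    flank5: str,
    flank3: str,
    reference_fasta: Path | str,
    workdir: Path | str | None = None,
    ambiguity_margin: float = AMBIGUITY_MARGIN,
    min_len: int = MIN_FLANK_FOR_MAPPING,
) -> tuple[FlankMapping | None, FlankMapping | None]:
    """Best unique reference placement of each flank; a second hit with
    >= (1 - margin) of the best score flags the flank as ambiguous."""
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        queries = []
        if len(flank5) >= min_len:
            queries.append(("flank5", flank5))
        if len(flank3) >= min_len:
            queries.append(("flank3", flank3))
        if not queries:
            return None, None
        q_fa = write_fasta(wd / "flanks.fa", queries)
        paf = run_minimap2(reference_fasta, q_fa, wd / "flanks.paf",
                           preset="map-pb", sam=False, base_level=True,
                           secondary=True)
        by_query: dict[str, list] = defaultdict(list)
        for hit in paf_records(paf):
            by_query[hit.query].append(hit)

        def best_of(name: str) -> FlankMapping | None:
            hits = by_query.get(name)
            if not hits:
                return None
            hits.sort(key=lambda h: -h.matches)
            top = hits[0]
            ambiguous = len(hits) > 1 and hits[1].matches >= (1 - ambiguity_margin) * top.matches
            return FlankMapping(
                contig=top.target,
                start=top.target_start,
                end=top.target_end,
                strand=top.strand,
                query_length=top.query_length,
                query_start=top.query_start,
                query_end=top.query_end,
                ambiguous=ambiguous,
            )

        return best_of("flank5"), best_of("flank3")
    finally:
        if ctx:
            ctx.cleanup()


def resolve_breakpoint(
    flank5: FlankMapping | None,
    flank3: FlankMapping | None,
    overlap_threshold: int = DEFAULT_OVERLAP_THRESHOLD,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    reference: Mapping[str, str] | None = None,
) -> BreakpointResolution:
    """Resolve insertion coordinates and TSD from the two flank placements.

    An overlap of o bp (0 < o <= overlap_threshold) between the flank
    placements defines a TSD of length o and the insertion interval; a
    gap of g bp (0 < g <= gap_threshold) defines the insertion interval
    with no TSD; larger overlaps/gaps are reported with non-resolved
    status.  Flanks on different contigs or in inconsistent orientation
    raise ``ValueError`` (the candidate is rejected).
    """
    if flank5 is None and flank3 is None:
        raise ValueError("both flanks unalignable: candidate unplaced")
    if flank5 is None or flank3 is None:
        fm = flank5 or flank3
        pos = fm.end if flank5 is not None else fm.start
        return BreakpointResolution(fm.contig, pos, pos, None, 0,
                                    STATUS_ONE_FLANK_ONLY)
    if flank5.contig != flank3.contig:
        raise ValueError("flanks map to different reference contigs")
    if flank5.strand != flank3.strand:
        raise ValueError("flanks map in inconsistent orientation")

    if flank5.strand == "+":
        # junction = 3' end of flank5 / 5' start of flank3 (clip-adjusted)
        jup = flank5.end + (flank5.query_length - flank5.query_end)
        jdown = flank3.start - flank3.query_start
    else:
        jup = flank3.end + flank3.query_start
        jdown = flank5.start - (flank5.query_length - flank5.query_end)
    if jdown - jup > max(len_span(flank5), gap_threshold) + 10_000:
        raise ValueError("flank order inconsistent with an insertion")

    overlap = jup - jdown
    if overlap > overlap_threshold:
        return BreakpointResolution(flank5.contig, jdown, jup, None, 0,
                                    STATUS_OVERLAP_EXCEEDED)
    if overlap >= 0:
        tsd_seq = None
        if overlap > 0 and reference is not None:
            tsd_seq = reference[flank5.contig][jdown:jup]
        return BreakpointResolution(flank5.contig, jdown, jup, tsd_seq,
                                    overlap, STATUS_RESOLVED)
    gap = -overlap
    if gap > gap_threshold:
        return BreakpointResolution(flank5.contig, jup, jdown, None, 0,
                                    STATUS_GAP_EXCEEDED)
    return BreakpointResolution(flank5.contig, jup, jdown, None, 0,
                                STATUS_RESOLVED)


def len_span(fm: FlankMapping) -> int:
    return fm.end - fm.start
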