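"""Stage 4: intra-sample TE allele frequency (TAF) from junction read
depths, and integer allele copy number from local copy-number dosage.

Reads near the insertion breakpoints are re-aligned to the polished
contig in both orientations; the mean depth immediately on the flank
side versus the TE side of each junction gives
TAF = (5p_te_cov/5p_flank_cov + 3p_te_cov/3p_flank_cov) / 2.
Allele copy number is round(raw_TAF x local copy number), ties rounded
half away from zero.
"""

from __future__ import annotations

import logging
import math
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pysam

from .align import run_minimap2, sam_records
from .seqs import mean_depth, revcomp, write_fasta

log = logging.getLogger("longte.quantify")

DEFAULT_EXTRACT_WINDOW = 1000
DEFAULT_COVERAGE_WINDOW = 100
DEFAULT_CN_FLANK_SPAN = 1000

FLAG_ONE_SIDED = "one_sided_taf"
FLAG_UNDEFINED = "taf_undefined"
FLAG_CLAMPED = "taf_clamped"
FLAG_WINDOW_SHRUNK = "coverage_window_shrunk"
FLAG_CN_DEFAULTED = "cn_defaulted"


@dataclass
class JunctionCoverage:
    p5_flank_cov: float
    p5_te_cov: float
    p3_flank_cov: float
    p3_te_cov: float
    window_bp: int
    flags: set[str] = field(default_factory=set)


@dataclass
class TafResult:
    raw_taf: float | None
    taf: float | None
    flags: set[str]


@dataclass
class TECall:
    """Final per-insertion record on reference coordinates."""

    id: str
    contig: str
    start: int
    end: int
    family: str
    strand: str
    tsd_sequence: str | None
    tsd_length: int
    status: str
    te_sequence: str
    support_count: int
    junction: JunctionCoverage | None = None
    raw_taf: float | None = None
    taf: float | None = None
    local_cn: float | None = None
    allele_copy_number: int | None = None
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        d = {
            "id": self.id,
            "contig": self.contig,
            "start": self.start,
            "end": self.end,
            "family": self.family,
            "strand": self.strand,
            "tsd_sequence": self.tsd_sequence,
            "tsd_length": self.tsd_length,
            "status": self.status,
            "te_length": len(self.te_sequence),
            "te_sequence": self.te_sequence,
            "support_count": self.support_count,
            "raw_taf": self.raw_taf,
            "taf": self.taf,
            "local_cn": self.local_cn,
            "allele_copy_number": self.allele_copy_number,
            "flags": sorted(self.flags),
        }
        if self.junction:
            d["junction"] = {
                "p5_flank_cov": self.junction.p5_flank_cov,
                "p5_te_cov": self.junction.p5_te_cov,
                "p3_flank_cov": self.junction.p3_flank_cov,
                "p3_te_cov": self.junction.p3_te_cov,
                "window_bp": self.junction.window_bp,
            }
        return d


class CNProfile:
    """Copy-number segments (contig, start, end, dosage), 0-based
    half-open, non-overlapping and sorted per contig.  Positions falling
    in gaps take a configurable default ploidy."""

    def __init__(self, segments: list[tuple[str, int, int, float]]):
        self.segments: dict[str, list[tuple[int, int, float]]] = {}
        for contig, start, end, cn in segments:
            if cn < 0:
                raise ValueError("copy number must be >= 0")
            self.segments.setdefault(contig, []).append((start, end, cn))
        for contig, segs in self.segments.items():
            segs.sort()
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping CN segments on {contig}")

    @classmethod
    def from_tsv(cls, path) -> "CNProfile":
        segs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                contig, start, end, cn = line.split("\t")[:4]
                segs.append((contig, int(start), int(end), float(cn)))
        return cls(segs)

    def mean_over(self, contig: str, start: int, end: int, default: float) -> float:
        """Length-weighted mean dosage over [start, end)."""
        if end <= start:
            return default
        segs = self.segments.get(contig)
        total = 0.0
        covered = 0
        if segs:
            for s, e, cn in segs:
                lo, hi = max(s, start), min(e, end)
                if hi > lo:
                    total += cn * (hi - lo)
                    covered += hi - lo
        gap = (end - start) - covered
        total += default * gap
        return total / (end - start)


def extract_nearby_reads(
    bam_path: Path | str,
    contig: str,
    start: int,
    end: int,
    window: int = DEFAULT_EXTRACT_WINDOW,
) -> dict[str, str]:
    """All reads whose alignment overlaps [start - window, end + window),
    each returned once (sequence in reference-forward orientation)."""
    out: dict[str, str] = {}
    with pysam.AlignmentFile(str(bam_path)) as fh:
        for rec in fh.fetch(contig, max(0, start - window), end + window):
            if rec.is_secondary or rec.is_unmapped:
                continue
            if rec.query_name in out:
                continue
            seq = rec.query_sequence
            if seq:
                out[rec.query_name] = seq
    return out


def _depth_profile(sam_path: Path, length: int) -> np.ndarray:
    depth = np.zeros(length, dtype=np.int32)
    for rec in sam_records(sam_path):
        rp = rec.reference_start
        for op, ln in rec.cigartuples:
            if op in (0, 7, 8):
                depth[rp : rp + ln] += 1
                rp += ln
            elif op in (2, 3):
                rp += ln
    return depth


def junction_coverages(
    reads: Mapping[str, str],
    contig_sequence: str,
    te_interval: tuple[int, int],
    window_bp: int = DEFAULT_COVERAGE_WINDOW,
    workdir: Path | str | None = None,
) -> JunctionCoverage:
    """Mean read depth over ``window_bp`` windows on each side of both
    TE junctions.  The 5' junction is measured with reads aligned to the
    forward contig; the 3' junction with reads aligned to its reverse
    complement (clipped/spanning reads beyond a 3' junction are better
    recovered that way); spanning reads contribute to both junctions."""
    ts, te = te_interval
    L = len(contig_sequence)
    if not (0 < ts < te < L):
        raise ValueError("TE interval must be strictly inside the contig")
    flags: set[str] = set()
    w = min(window_bp, ts, te - ts, L - te)
    if w < window_bp:
        flags.add(FLAG_WINDOW_SHRUNK)
    if not reads:
        return JunctionCoverage(0.0, 0.0, 0.0, 0.0, w, flags)

    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    try:
        reads_fa = write_fasta(wd / "taf_reads.fa", reads.items())

        def pass_depth(seq: str, tag: str) -> np.ndarray:
            fa = write_fasta(wd / f"taf_contig_{tag}.fa", [(f"contig_{tag}", seq)])
            sam = run_minimap2(fa, reads_fa, wd / f"taf_{tag}.sam",
                               preset="map-pb", sam=True)
            return _depth_profile(sam, len(seq))

        fw = pass_depth(contig_sequence, "fw")
        rc = pass_depth(revcomp(contig_sequence), "rc")
        p5_flank = mean_depth(fw, ts - w, ts)
        p5_te = mean_depth(fw, ts, ts + w)
        ts_rc = L - te  # 3' junction position on the reverse complement
        p3_flank = mean_depth(rc, ts_rc - w, ts_rc)
        p3_te = mean_depth(rc, ts_rc, ts_rc + w)
        return JunctionCoverage(p5_flank, p5_te, p3_flank, p3_te, w, flags)
    finally:
        if ctx:
            ctx.cleanup()


def estimate_taf(j: JunctionCoverage) -> TafResult:
    """TAF = (5p_te/5p_flank + 3p_te/3p_flank)/2; a single zero-coverage
    flank falls back to the one-sided ratio (flagged); both zero leaves
    the TAF undefined (distinct from 0)."""
    flags: set[str] = set()
    r5 = j.p5_te_cov / j.p5_flank_cov if j.p5_flank_cov > 0 else None
    r3 = j.p3_te_cov / j.p3_flank_cov if j.p3_flank_cov > 0 else None
    if r5 is None and r3 is None:
        return TafResult(None, None, {FLAG_UNDEFINED})
    if r5 is None or r3 is None:
        raw = r5 if r5 is not None else r3
        flags.add(FLAG_ONE_SIDED)
    else:
        raw = (r5 + r3) / 2.0
    taf = min(max(raw, 0.0), 1.0)
    if raw > 1.0:
        flags.add(FLAG_CLAMPED)
    return TafResult(raw, taf, flags)


def local_copy_number(
    cn: CNProfile | None,
    contig: str,
    start: int,
    end: int,
    flank_span: int = DEFAULT_CN_FLANK_SPAN,
    default_ploidy: float = 2.0,
) -> tuple[float, set[str]]:
    """Length-weighted mean dosage over the two ``flank_span`` windows
    flanking the insertion interval (the interval itself excluded)."""
    flags: set[str] = set()
    if cn is None or contig not in cn.segments:
        if cn is not None:
            flags.add(FLAG_CN_DEFAULTED)
        return float(default_ploidy), flags
    left = cn.mean_over(contig, max(0, start - flank_span), start, default_ploidy)
    right = cn.mean_over(contig, end, end + flank_span, default_ploidy)
    left_len = start - max(0, start - flank_span)
    total = left_len + flank_span
    value = (left * left_len + right * flank_span) / total if total else default_ploidy
    return value, flags


def allele_copy_number(raw_taf: float, local_cn: float) -> int:
    """round(raw_TAF x local CN), ties rounded half away from zero."""
    v = raw_taf * local_cn
    return max(0, int(math.floor(v + 0.5)))
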