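"""Adapter around the minimap2 long-read aligner.

All alignment steps in the pipeline (reads vs reference, reads vs local
contig, TE library vs insert/contig, flanks vs reference) go through
this module; SAM output is parsed with pysam and PAF output with a
minimal record reader.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pysam

log = logging.getLogger("longte.align")

MINIMAP2 = "minimap2"


def minimap2_available() -> bool:
    return shutil.which(MINIMAP2) is not None


def run_minimap2(
    target: Path | str,
    query: Path | str,
    out: Path | str,
    preset: str = "map-pb",
    sam: bool = True,
    base_level: bool = False,
    threads: int = 1,
    secondary: bool = False,
    extra: Sequence[str] = (),
) -> Path:
    """Run minimap2 and write SAM (``-a -Y``) or PAF; secondary
    alignments are off unless requested."""
    if not minimap2_available():
        raise RuntimeError("minimap2 not found on PATH")
    out = Path(out)
    cmd = [MINIMAP2, "-x", preset, "-t", str(threads), "-K", "50m"]
    if secondary:
        cmd += ["--secondary=yes", "-p", "0.3", "-N", "10"]
    else:
        cmd += ["--secondary=no"]
    if sam:
        cmd += ["-a", "-Y"]
    elif base_level:
        cmd += ["-c"]
    cmd += list(extra)
    cmd += [str(target), str(query)]
    with open(out, "w") as fh:
        proc = subprocess.run(cmd, stdout=fh, stderr=subprocess.PIPE, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"minimap2 failed ({proc.returncode}): {proc.stderr.strip().splitlines()[-1:]}"
        )
    return out


def sam_records(sam_path: Path | str) -> Iterator[pysam.AlignedSegment]:
    """Iterate mapped, non-secondary records of a SAM/BAM file."""
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            yield rec


def sort_and_index(sam_path: Path | str, bam_path: Path | str) -> Path:
    bam_path = Path(bam_path)
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


@dataclass(frozen=True)
class PafHit:
    query: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target: str
    target_length: int
    target_start: int
    target_end: int
    matches: int
    alignment_length: int

    @property
    def identity(self) -> float:
        return self.matches / self.alignment_length if self.alignment_length else 0.0


def paf_records(path: Path | str) -> Iterator[PafHit]:
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            yield PafHit(
                query=f[0],
                query_length=int(f[1]),
                query_start=int(f[2]),
                query_end=int(f[3]),
                strand=f[4],
                target=f[5],
                target_length=int(f[6]),
                target_start=int(f[7]),
                target_end=int(f[8]),
                matches=int(f[9]),
                alignment_length=int(f[10]),
            )


def merged_span(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total
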