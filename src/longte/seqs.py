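"""Small sequence utilities shared across the pipeline.

All sequences are uppercase A/C/G/T strings; numeric code arrays (uint8,
A=0 C=1 G=2 T=3) are used internally where vectorised mutation or
consensus counting is needed.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _LUT[arr]
    if (codes == 255).any():
        bad = chr(arr[codes == 255][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> Path:
    """Write (name, sequence) pairs as FASTA."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> sequence mapping."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ file (plain or gzipped)."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def read_fastq(path) -> dict[str, str]:
    return dict(iter_fastq(path))


def mean_depth(depth: np.ndarray, start: int, end: int) -> float:
    """Mean of a per-position depth array over [start, end), clipped to bounds."""
    start = max(0, start)
    end = min(len(depth), end)
    if end <= start:
        return 0.0
    return float(depth[start:end].mean())
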