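"""Readers and writers for the pipeline's external formats: final calls
as VCF 4.2 / BED6+ / JSON lines, candidate JSON lines, and truth tables
(see :mod:`longte.simulate` for the truth writers)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from .quantify import JunctionCoverage, TECall

VCF_INFO_KEYS = (
    "FAMILY", "STRAND", "TSD_LEN", "TSD_SEQ", "TAF", "RAW_TAF", "CN", "ACN",
    "STATUS", "SUPPORT",
)


def _fmt(value, digits: int = 4):
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:.{digits}g}"
    return str(value)


def write_calls_vcf(
    calls: Sequence[TECall],
    path,
    reference: Mapping[str, str],
    source: str = "longte",
) -> Path:
    """VCF 4.2; POS is the 1-based coordinate of the last reference base
    before the insertion interval (i.e. the 0-based interval start)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        for key, typ, desc in (
            ("FAMILY", "String", "TE family of the inserted sequence"),
            ("STRAND", "String", "TE strand relative to the reference"),
            ("TSD_LEN", "Integer", "Target site duplication length"),
            ("TSD_SEQ", "String", "Target site duplication sequence"),
            ("TAF", "Float", "TE allele frequency (clamped to [0,1])"),
            ("RAW_TAF", "Float", "Unclamped TE allele frequency"),
            ("CN", "Float", "Local copy number dosage at the locus"),
            ("ACN", "Integer", "TE allele copy number"),
            ("STATUS", "String", "Breakpoint resolution status"),
            ("SUPPORT", "Integer", "Supporting read count"),
        ):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(calls, key=lambda c: (c.contig, c.start)):
            pos1 = call.start  # 1-based position of the base before the interval
            ref_base = (
                reference[call.contig][call.start - 1]
                if 0 < call.start <= len(reference[call.contig])
                else "N"
            )
            info = ";".join(
                f"{k}={v}"
                for k, v in (
                    ("FAMILY", call.family),
                    ("STRAND", call.strand),
                    ("TSD_LEN", call.tsd_length),
                    ("TSD_SEQ", call.tsd_sequence or "."),
                    ("TAF", _fmt(call.taf)),
                    ("RAW_TAF", _fmt(call.raw_taf)),
                    ("CN", _fmt(call.local_cn)),
                    ("ACN", _fmt(call.allele_copy_number)),
                    ("STATUS", call.status),
                    ("SUPPORT", call.support_count),
                )
            )
            fh.write(
                f"{call.contig}\t{pos1}\t{call.id}\t{ref_base}\t<INS>\t.\tPASS\t{info}\n"
            )
    return path


def read_calls_vcf(path) -> list[TECall]:
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info

            def get(key, cast=None):
                v = info.get(key)
                if v in (None, ".", ()):
                    return None
                if isinstance(v, tuple):
                    v = v[0]
                if v in (None, "."):
                    return None
                return cast(v) if cast else v

            taf = get("TAF", float)
            calls.append(
                TECall(
                    id=rec.id or f"{rec.contig}_{rec.pos}",
                    contig=rec.contig,
                    start=rec.pos,  # POS is the base before the interval
                    end=rec.pos + (get("TSD_LEN", int) or 0),
                    family=get("FAMILY") or "",
                    strand=get("STRAND") or ".",
                    tsd_sequence=get("TSD_SEQ"),
                    tsd_length=get("TSD_LEN", int) or 0,
                    status=get("STATUS") or "resolved",
                    te_sequence="",
                    support_count=get("SUPPORT", int) or 0,
                    raw_taf=get("RAW_TAF", float),
                    taf=taf,
                    local_cn=get("CN", float),
                    allele_copy_number=get("ACN", int),
                )
            )
    return calls


def write_calls_bed(calls: Sequence[TECall], path) -> Path:
    """BED6+ (0-based half-open): extra columns family-agnostic payload."""
    path = Path(path)
    with open(path, "w") as fh:
        for call in sorted(calls, key=lambda c: (c.contig, c.start)):
            fh.write(
                "\t".join(
                    [
                        call.contig,
                        str(call.start),
                        str(call.end),
                        call.id,
                        "0",
                        call.strand,
                        call.family,
                        str(call.tsd_length),
                        _fmt(call.taf),
                        _fmt(call.allele_copy_number),
                        call.status,
                    ]
                )
                + "\n"
            )
    return path


def read_calls_bed(path) -> list[TECall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(
                TECall(
                    id=f[3],
                    contig=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    family=f[6],
                    strand=f[5],
                    tsd_sequence=None,
                    tsd_length=int(f[7]),
                    status=f[10],
                    te_sequence="",
                    support_count=0,
                    taf=None if f[8] == "." else float(f[8]),
                    allele_copy_number=None if f[9] == "." else int(f[9]),
                )
            )
    return calls


def write_calls_json(calls: Sequence[TECall], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for call in sorted(calls, key=lambda c: (c.contig, c.start)):
            fh.write(json.dumps(call.to_dict()) + "\n")
    return path


def read_calls_json(path) -> list[TECall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            junction = None
            if d.get("junction"):
                junction = JunctionCoverage(**d["junction"])
            calls.append(
                TECall(
                    id=d["id"],
                    contig=d["contig"],
                    start=d["start"],
                    end=d["end"],
                    family=d["family"],
                    strand=d["strand"],
                    tsd_sequence=d["tsd_sequence"],
                    tsd_length=d["tsd_length"],
                    status=d["status"],
                    te_sequence=d.get("te_sequence", ""),
                    support_count=d["support_count"],
                    junction=junction,
                    raw_taf=d["raw_taf"],
                    taf=d["taf"],
                    local_cn=d["local_cn"],
                    allele_copy_number=d["allele_copy_number"],
                    flags=set(d.get("flags", ())),
                )
            )
    return calls


def write_calls(calls: Sequence[TECall], path, fmt: str,
                reference: Mapping[str, str] | None = None) -> Path:
    if fmt == "vcf":
        if reference is None:
            raise ValueError("writing VCF requires the reference sequences")
        return write_calls_vcf(calls, path, reference)
    if fmt == "bed":
        return write_calls_bed(calls, path)
    if fmt == "json":
        return write_calls_json(calls, path)
    raise ValueError(f"unknown format {fmt!r}")


def write_candidates_json(candidates, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for cand in candidates:
            fh.write(json.dumps(cand.to_dict()) + "\n")
    return path
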