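"""Family-level TE sequence phylogenetics: full-length filtering, MSA,
spurious-row trimming, tree building with bootstrap support, and
single- vs multi-source expansion-clade classification.

A family expansion is called single-source when the new (cell-line
specific, allele-copy-number-one) insertions form one well-supported
monophyletic clade; multiple qualifying clades indicate multiple source
lineages.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqs import read_fasta, write_fasta
from .telib import TELibrary

log = logging.getLogger("longte.phylo")

DEFAULT_RATIO_BOUNDS = (0.95, 1.05)
FAMILY_RATIO_OVERRIDES = {"297": (0.75, 1.05)}
DEFAULT_RESOVERLAP = 0.75
DEFAULT_SEQOVERLAP = 80.0
DEFAULT_MIN_INSERTIONS = 3
DEFAULT_MIN_BOOTSTRAP = 50.0
DEFAULT_MIN_PROP = 0.2

GAP = ord("-")

Msa = list[tuple[str, str]]


@dataclass
class FullLengthFilterConfig:
    """Criteria for retaining high-quality full-length TE sequences."""

    ratio_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(FAMILY_RATIO_OVERRIDES)
    )
    default_bounds: tuple[float, float] = DEFAULT_RATIO_BOUNDS
    region_mask: dict[str, list[tuple[int, int]]] | None = None
    require_both_flanks: bool = True
    require_taf: bool = True
    exclude_contigs: tuple[str, ...] = ()

    def bounds_for(self, family: str) -> tuple[float, float]:
        lo, hi = self.ratio_bounds.get(family, self.default_bounds)
        if not 0 < lo < hi:
            raise ValueError(f"invalid ratio bounds for {family}: ({lo}, {hi})")
        return lo, hi


@dataclass
class ExpansionClade:
    family: str
    members: list[str]
    n_members: int
    n_copy_number_one_cellline: int
    bootstrap: float
    prop_cn1: float
    verdict: str = "expansion"


@dataclass
class TreeResult:
    tree: object  # skbio.TreeNode, unrooted
    supports: dict[frozenset, float]  # canonical bipartition -> percent
    ids: list[str]
    star: bool = False


def filter_full_length(
    calls: Sequence,
    te_library: TELibrary,
    cfg: FullLengthFilterConfig | None = None,
) -> tuple[dict[str, Msa], Counter]:
    """Apply the full-length sequence filters to final TE calls.

    A call is retained iff its contig is not excluded, its locus lies in
    the region mask (when one is configured), its assembled TE length /
    canonical length ratio lies within the family bounds, both flanks
    mapped (resolved breakpoint), and a TAF was estimated.  Returns
    per-family (id, sequence) lists and a tally of rejection reasons.
    """
    cfg = cfg or FullLengthFilterConfig()
    reasons: Counter = Counter()
    by_family: dict[str, list[tuple[str, str]]] = {}
    for call in calls:
        if call.contig in cfg.exclude_contigs:
            reasons["excluded_contig"] += 1
            continue
        if cfg.region_mask is not None:
            regions = cfg.region_mask.get(call.contig, [])
            if not any(s <= call.start and call.end <= e for s, e in regions):
                reasons["outside_region_mask"] += 1
                continue
        if call.family not in te_library:
            reasons["unknown_family"] += 1
            continue
        lo, hi = cfg.bounds_for(call.family)
        ratio = len(call.te_sequence) / te_library.canonical_length(call.family)
        if not lo <= ratio <= hi:
            reasons["length_ratio"] += 1
            continue
        if cfg.require_both_flanks and call.status != "resolved":
            reasons["flanks_unmapped"] += 1
            continue
        if cfg.require_taf and call.taf is None:
            reasons["no_taf"] += 1
            continue
        by_family.setdefault(call.family, []).append((call.id, call.te_sequence))
        reasons["retained"] += 1
    return by_family, reasons


# ---------------------------------------------------------------------------
# multiple sequence alignment


def _mafft_available() -> bool:
    return shutil.which("mafft") is not None


def _mafft_align(seqs: Msa) -> Msa:
    with tempfile.TemporaryDirectory() as td:
        inp = write_fasta(Path(td) / "in.fa", seqs)
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(inp)],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"mafft failed: {proc.stderr.strip()[:200]}")
        out = Path(td) / "out.fa"
        out.write_text(proc.stdout)
        aligned = read_fasta(out)
    return [(name, aligned[name].upper()) for name, _ in seqs]


def _center_star_align(seqs: Msa) -> Msa:
    """Built-in progressive alignment: global pairwise alignments of all
    rows against the centre sequence (minimum total edit distance),
    merged under once-a-gap-always-a-gap."""
    import edlib

    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i][1], seqs[j][1], mode="NW", task="distance")
            dist[i, j] = dist[j, i] = d["editDistance"]
    center = int(dist.sum(axis=1).argmin())
    center_seq = seqs[center][1]
    m = len(center_seq)

    # per-row gap pattern relative to the centre
    row_ins: list[dict[int, str]] = []  # centre position -> inserted run
    row_aln: list[list[str | None]] = []  # aligned char per centre position
    for i in range(n):
        if i == center:
            row_ins.append({})
            row_aln.append(list(center_seq))
            continue
        res = edlib.align(seqs[i][1], center_seq, mode="NW", task="path")
        ins: dict[int, str] = {}
        aln: list[str | None] = [None] * m
        qp = cp = 0
        q = seqs[i][1]
        import re

        for ln_s, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
            ln = int(ln_s)
            if op in "=XM":
                for k in range(ln):
                    aln[cp + k] = q[qp + k]
                qp += ln
                cp += ln
            elif op == "D":  # gap in query: centre advances
                cp += ln
            elif op == "I":  # gap in centre: query insertion before cp
                ins[cp] = ins.get(cp, "") + q[qp : qp + ln]
                qp += ln
        row_ins.append(ins)
        row_aln.append(aln)

    master_ins = {}
    for ins in row_ins:
        for cp, run in ins.items():
            master_ins[cp] = max(master_ins.get(cp, 0), len(run))

    out: Msa = []
    for i in range(n):
        parts: list[str] = []
        for cp in range(m + 1):
            pad = master_ins.get(cp, 0)
            if pad:
                run = row_ins[i].get(cp, "")
                parts.append(run + "-" * (pad - len(run)))
            if cp < m:
                ch = row_aln[i][cp]
                parts.append(ch if ch is not None else "-")
        out.append((seqs[i][0], "".join(parts)))
    return out


def build_family_alignment(seqs: Msa, engine: str = "auto") -> Msa:
    """Align a family's sequences (>= 3 required).  ``engine`` is
    ``mafft`` (external), ``builtin`` (centre-star) or ``auto``."""
    if len(seqs) < 3:
        raise ValueError(f"need >= 3 sequences, got {len(seqs)}")
    if engine == "auto":
        engine = "mafft" if _mafft_available() else "builtin"
    if engine == "mafft":
        return _mafft_align(seqs)
    if engine == "builtin":
        return _center_star_align(seqs)
    raise ValueError(f"unknown alignment engine {engine!r}")


def _msa_matrix(msa: Msa) -> np.ndarray:
    lengths = {len(row) for _, row in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    return np.frombuffer("".join(r for _, r in msa).encode(), np.uint8).reshape(
        len(msa), -1
    )


def trim_alignment(
    msa: Msa,
    resoverlap: float = DEFAULT_RESOVERLAP,
    seqoverlap: float = DEFAULT_SEQOVERLAP,
) -> tuple[Msa, list[str]]:
    """Remove spurious rows from an alignment.

    A residue's overlap score is the fraction of other rows with the
    same character at that column (a gap matches a gap); a row is kept
    iff at least ``seqoverlap`` percent of its residues score >=
    ``resoverlap``.  Raises when every row would be removed.
    """
    M = _msa_matrix(msa)
    n = len(msa)
    if n == 1:
        return list(msa), []
    eq = M[:, None, :] == M[None, :, :]
    # mean over other rows only
    score = (eq.sum(axis=1) - 1) / (n - 1)
    keep_idx = []
    removed = []
    for i in range(n):
        residues = M[i] != GAP
        if residues.sum() == 0:
            removed.append(msa[i][0])
            continue
        frac = float((score[i][residues] >= resoverlap).mean()) * 100.0
        if frac >= seqoverlap:
            keep_idx.append(i)
        else:
            removed.append(msa[i][0])
    if not keep_idx:
        raise ValueError("all rows removed: alignment unusable")
    return [msa[i] for i in keep_idx], removed


# ---------------------------------------------------------------------------
# tree building (built-in neighbor joining + nonparametric bootstrap)


def _distance_matrix(M: np.ndarray) -> np.ndarray:
    nongap = M != GAP
    shared = (nongap[:, None, :] & nongap[None, :, :]).sum(axis=2)
    same = ((M[:, None, :] == M[None, :, :]) & nongap[:, None, :] & nongap[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - same / shared
    d[shared == 0] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def _nj_tree(d: np.ndarray, ids: list[str]):
    from skbio import DistanceMatrix
    from skbio.tree import nj

    return nj(DistanceMatrix(np.ascontiguousarray((d + d.T) / 2), ids))


def _bipartitions(tree, taxa: frozenset, ref: str) -> set[frozenset]:
    """Canonical non-trivial bipartitions of an (un)rooted tree: each
    side is keyed by the half not containing the reference taxon."""
    out = set()
    n = len(taxa)
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def build_tree(
    msa: Msa,
    bootstrap_replicates: int = 100,
    seed: int = 0,
) -> TreeResult:
    """Neighbor-joining tree on nucleotide p-distances with nonparametric
    (column-resampling) bootstrap support per internal bipartition."""
    if len(msa) < 3:
        raise ValueError("need >= 3 aligned rows to build a tree")
    ids = [name for name, _ in msa]
    M = _msa_matrix(msa)
    d = _distance_matrix(M)
    star = bool(np.allclose(d, 0.0))
    tree = _nj_tree(d, ids)
    taxa = frozenset(ids)
    ref = min(ids)
    supports: dict[frozenset, float] = {}
    if len(msa) >= 4 and not star:
        # precompute per-column pair agreement for fast resampling
        nongap = M != GAP
        eq = (M[:, None, :] == M[None, :, :]) & nongap[:, None, :] & nongap[None, :, :]
        both = nongap[:, None, :] & nongap[None, :, :]
        rng = np.random.default_rng(seed)
        counts: Counter = Counter()
        L = M.shape[1]
        for _ in range(bootstrap_replicates):
            cols = rng.integers(0, L, L)
            same = eq[:, :, cols].sum(axis=2)
            shared = both[:, :, cols].sum(axis=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                db = 1.0 - same / shared
            db[shared == 0] = 1.0
            np.fill_diagonal(db, 0.0)
            for bp in _bipartitions(_nj_tree(db, ids), taxa, ref):
                counts[bp] += 1
        for bp in _bipartitions(tree, taxa, ref):
            supports[bp] = 100.0 * counts.get(bp, 0) / bootstrap_replicates
    if star:
        log.warning("all sequences identical: star tree, supports undefined")
    return TreeResult(tree=tree, supports=supports, ids=ids, star=star)


def classify_expansions(
    tree_result: TreeResult,
    metadata: Mapping[str, tuple[str, int]],
    cellline_sample: str = "cellline",
    family: str = "",
    min_insertions: int = DEFAULT_MIN_INSERTIONS,
    min_bootstrap: float = DEFAULT_MIN_BOOTSTRAP,
    min_prop: float = DEFAULT_MIN_PROP,
    outgroup: str | None = None,
) -> list[ExpansionClade]:
    """Report maximal clades of single-source TE expansion.

    A clade qualifies when it holds at least ``min_insertions``
    cell-line-specific insertions (sample == ``cellline_sample`` and
    allele copy number == 1), has bootstrap support >= ``min_bootstrap``
    percent, and its proportion of such insertions is >= ``min_prop``.
    The unrooted tree is rooted at ``outgroup`` when given, otherwise at
    its midpoint; only maximal qualifying clades are reported, so the
    clade count equals the number of inferred source lineages.
    """
    tree = tree_result.tree
    for tip in tree.tips():
        if tip.name not in metadata:
            raise ValueError(f"missing metadata for leaf {tip.name!r}")
    if tree_result.star:
        return []
    taxa = frozenset(tree_result.ids)
    ref = min(tree_result.ids)
    n = len(taxa)

    rooted = tree.copy()
    try:
        if outgroup is not None:
            rooted = rooted.root_at(rooted.find(outgroup).parent)
        else:
            rooted = rooted.root_at_midpoint()
    except Exception:
        log.warning("rooting failed; using the tree as returned")

    def is_cl1(name: str) -> bool:
        sample, acn = metadata[name]
        return sample == cellline_sample and acn == 1

    qualifying: list[tuple[frozenset, ExpansionClade]] = []
    for node in rooted.traverse(include_self=False):
        if node.is_tip():
            continue
        tips = frozenset(t.name for t in node.tips())
        if len(tips) >= n:
            continue
        n_cl1 = sum(1 for t in tips if is_cl1(t))
        if n_cl1 < min_insertions:
            continue
        prop = n_cl1 / len(tips)
        if prop < min_prop:
            continue
        key = tips if ref not in tips else taxa - tips
        if 2 <= len(key) <= n - 2:
            support = tree_result.supports.get(key, 0.0)
        else:
            support = 100.0  # trivial bipartition: present in every tree
        if support < min_bootstrap:
            continue
        qualifying.append(
            (
                tips,
                ExpansionClade(
                    family=family,
                    members=sorted(tips),
                    n_members=len(tips),
                    n_copy_number_one_cellline=n_cl1,
                    bootstrap=support,
                    prop_cn1=prop,
                ),
            )
        )

    maximal = []
    for tips, clade in qualifying:
        if any(tips < other for other, _ in qualifying):
            continue
        maximal.append(clade)
    return maximal


# built-in normal-recombination region mask used in the original study
# (dm6 coordinates); provided as data for real-genome runs
NORMAL_RECOMBINATION_REGIONS: dict[str, list[tuple[int, int]]] = {
    "chrX": [(405_967, 20_928_973)],
    "chr2L": [(200_000, 20_100_000)],
    "chr2R": [(6_412_495, 25_112_477)],
    "chr3L": [(100_000, 21_906_900)],
    "chr3R": [(4_774_278, 31_974_278)],
}
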