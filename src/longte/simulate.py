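"""Synthetic polyploid genomes carrying TE insertions, long reads, and
diverged TE lineages.

The generator emulates the study conditions the pipeline is designed for:
a polyploid genome (ploidy 1-4) in which non-reference TE insertions sit
on a subset of haplotypes (carrier fraction k/p gives an expected allele
frequency of k/p), every insertion creates an exact target-site
duplication, and the sample is sequenced with PacBio-like long reads
(log-normal lengths, indel-dominant errors).  Ground truth is emitted as
machine-readable :class:`TruthRecord` tables so every downstream stage
can be scored without external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from io import StringIO
from pathlib import Path

import numpy as np

from .seqs import BASES, revcomp, to_codes, to_str
from .telib import TEFamily, TELibrary

REFERENCE_NAME = "chr1"
MIN_REFERENCE_LENGTH = 10_000
MIN_READ_LENGTH = 500
MAX_ERROR_RATE = 0.3


@dataclass
class SimConfig:
    """Parameters of one simulated sequencing experiment.

    ``zygosity_spec`` lists the number of carrier haplotypes per planted
    insertion (1..ploidy); ``None`` cycles 1..ploidy so every zygosity
    class is represented.  ``depth_total`` is fold coverage summed over
    all haplotypes, split equally among them.  ``error_mix`` is the
    (insertion, deletion, substitution) share of the per-base error rate.
    """

    reference_length: int = 2_000_000
    ploidy: int = 4
    n_insertions: int = 40
    zygosity_spec: list[int] | None = None
    depth_total: float = 125.0
    read_length_mean: float = 8_000.0
    read_length_sd: float = 5_000.0
    error_rate: float = 0.09
    error_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    min_end_distance: int = 2_000
    homopolymer_cap: int = 20

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.depth_total <= 0:
            raise ValueError("depth_total must be > 0")
        if self.zygosity_spec is not None:
            if len(self.zygosity_spec) != self.n_insertions:
                raise ValueError("zygosity_spec length must equal n_insertions")
            for k in self.zygosity_spec:
                if not 1 <= k <= self.ploidy:
                    raise ValueError(f"carrier count {k} outside 1..ploidy")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must sum to 1")

    def carrier_counts(self) -> list[int]:
        if self.zygosity_spec is not None:
            return list(self.zygosity_spec)
        return [(i % self.ploidy) + 1 for i in range(self.n_insertions)]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted insertion, on unmodified-reference
    coordinates (0-based insertion point)."""

    contig: str
    position: int
    family: str
    strand: str
    tsd_length: int
    carrier_haplotypes: frozenset[int]
    true_taf: float
    true_allele_copy_number: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["carrier_haplotypes"] = sorted(self.carrier_haplotypes)
        return d


def _random_codes(length: int, rng: np.random.Generator, cap: int) -> np.ndarray:
    codes = rng.integers(0, 4, length, dtype=np.uint8)
    # break any homopolymer run longer than `cap` (degenerate for alignment)
    while True:
        change = np.flatnonzero(np.diff(codes) != 0)
        starts = np.concatenate(([0], change + 1))
        lengths = np.diff(np.concatenate((starts, [length])))
        bad = np.flatnonzero(lengths > cap)
        if bad.size == 0:
            return codes
        for i in bad:
            s, ln = int(starts[i]), int(lengths[i])
            for p in range(s + cap, s + ln, cap):
                codes[p] = (codes[p] + rng.integers(1, 4)) % 4


def make_reference(length: int, seed: int, homopolymer_cap: int = 20) -> str:
    """Generate a random reference sequence; deterministic per seed."""
    if length < MIN_REFERENCE_LENGTH:
        raise ValueError(
            f"reference too short: {length} < {MIN_REFERENCE_LENGTH} bp minimum"
        )
    rng = np.random.default_rng(seed)
    return to_str(_random_codes(length, rng, homopolymer_cap))


_DEFAULT_FAMILIES: list[tuple[str, str, int, int | tuple[int, int]]] = [
    # (name, superfamily, canonical length, TSD model)
    ("gypsy", "Gypsy", 5_000, 4),
    ("297", "Gypsy", 4_500, 4),
    ("copia", "Copia", 4_200, 5),
    ("roo", "Pao", 4_800, 5),
    ("jockey", "Jockey", 3_600, (8, 12)),
    ("juan", "Jockey", 3_000, (8, 12)),
]


def synthetic_te_library(seed: int = 7) -> TELibrary:
    """A synthetic stand-in for a curated TE library: six families with
    realistic canonical lengths and superfamily-typical TSD models."""
    rng = np.random.default_rng(seed)
    fams = []
    for name, sup, length, tsd in _DEFAULT_FAMILIES:
        seq = to_str(_random_codes(length, rng, 20))
        fams.append(TEFamily(name, seq, superfamily=sup, tsd=tsd))
    return TELibrary(fams)


def _draw_sites(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Insertion sites >= min_end_distance from the ends and separated by
    at least 2x the mean read length, drawn without replacement."""
    n = config.n_insertions
    min_gap = int(2 * config.read_length_mean)
    lo = config.min_end_distance
    hi = config.reference_length - config.min_end_distance
    span = hi - lo - (n - 1) * min_gap
    if span <= n:
        raise ValueError(
            f"cannot place {n} insertions with {min_gap} bp spacing "
            f"in a {config.reference_length} bp reference"
        )
    u = np.sort(rng.choice(span, size=n, replace=False))
    return lo + u + np.arange(n) * min_gap


def plant_insertions(
    reference: str,
    te_library: TELibrary,
    config: SimConfig,
) -> tuple[list[str], list[TruthRecord]]:
    """Plant TE insertions with exact TSDs on chosen haplotype subsets.

    Returns one sequence per haplotype plus the truth table.  Each
    carrier haplotype receives the canonical family sequence (reverse
    complemented for minus-strand insertions) flanked by a duplication of
    the ``tsd_length`` bases at the site; non-carriers are untouched
    there.  Truth coordinates refer to the unmodified reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sites = _draw_sites(rng, config)
    counts = config.carrier_counts()
    names = te_library.names

    truths: list[TruthRecord] = []
    placements = []  # (position, tsd_len, te_seq, carriers)
    for pos, k in zip(sites, counts):
        fam = te_library[names[rng.integers(len(names))]]
        strand = "+" if rng.random() < 0.5 else "-"
        tsd_len = fam.draw_tsd_length(rng)
        carriers = frozenset(
            int(h) for h in rng.choice(config.ploidy, size=k, replace=False)
        )
        te_seq = fam.sequence if strand == "+" else revcomp(fam.sequence)
        placements.append((int(pos), tsd_len, te_seq, carriers))
        truths.append(
            TruthRecord(
                contig=REFERENCE_NAME,
                position=int(pos),
                family=fam.name,
                strand=strand,
                tsd_length=tsd_len,
                carrier_haplotypes=carriers,
                true_taf=k / config.ploidy,
                true_allele_copy_number=k,
            )
        )

    haplotypes = []
    for h in range(config.ploidy):
        parts = []
        cur = 0
        for pos, tsd_len, te_seq, carriers in placements:
            if h not in carriers:
                continue
            parts.append(reference[cur : pos + tsd_len])
            parts.append(te_seq)
            cur = pos  # re-emit [pos, pos+tsd) -> exact duplication
        parts.append(reference[cur:])
        haplotypes.append("".join(parts))
    return haplotypes, truths


def _mutate(
    codes: np.ndarray,
    rng: np.random.Generator,
    rate: float,
    mix: tuple[float, float, float],
) -> np.ndarray:
    """Apply i.i.d. per-base errors (insertion/deletion/substitution mix)."""
    if rate == 0:
        return codes
    n = len(codes)
    r = rng.random(n)
    p_ins = rate * mix[0]
    p_del = p_ins + rate * mix[1]
    ins_mask = r < p_ins
    del_mask = (r >= p_ins) & (r < p_del)
    sub_mask = (r >= p_del) & (r < rate)

    out_codes = codes.copy()
    subs = np.flatnonzero(sub_mask)
    out_codes[subs] = (out_codes[subs] + rng.integers(1, 4, subs.size)) % 4

    lens = np.ones(n, dtype=np.int64)
    lens[del_mask] = 0
    lens[ins_mask] += 1  # keep base, then one inserted base after it
    starts = np.cumsum(lens) - lens
    out = np.empty(int(lens.sum()), dtype=np.uint8)
    keep = ~del_mask
    out[starts[keep]] = out_codes[keep]
    ins_at = np.flatnonzero(ins_mask)
    out[starts[ins_at] + 1] = rng.integers(0, 4, ins_at.size).astype(np.uint8)
    return out


def simulate_reads(haplotypes: list[str], config: SimConfig, out_fastq) -> Path:
    """Sequence the haplotypes to ``depth_total`` (split equally), writing
    FASTQ.  Read names encode haplotype of origin, start and strand for
    truth tracking.  Deterministic per seed."""
    if config.error_rate >= MAX_ERROR_RATE:
        raise ValueError(
            f"error_rate {config.error_rate} >= {MAX_ERROR_RATE}: no aligner "
            "contract holds at that error level"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mu_ln = math.log(config.read_length_mean**2 /
                     math.sqrt(config.read_length_mean**2 + config.read_length_sd**2))
    sd_ln = math.sqrt(math.log(1 + (config.read_length_sd / config.read_length_mean) ** 2))
    per_hap_depth = config.depth_total / len(haplotypes)

    out_fastq = Path(out_fastq)
    i = 0
    with open(out_fastq, "w") as fh:
        for h, hap in enumerate(haplotypes):
            hap_codes = to_codes(hap)
            target = per_hap_depth * len(hap)
            emitted = 0
            while emitted < target:
                length = int(rng.lognormal(mu_ln, sd_ln))
                length = max(MIN_READ_LENGTH, min(length, len(hap)))
                start = int(rng.integers(0, len(hap) - length + 1))
                frag = hap_codes[start : start + length]
                read = _mutate(frag, rng, config.error_rate, config.error_mix)
                strand = "+" if rng.random() < 0.5 else "-"
                seq = to_str(read)
                if strand == "-":
                    seq = revcomp(seq)
                name = f"hap{h}_r{i}_{start}_{start + length}_{strand}"
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
                emitted += length
                i += 1
    return out_fastq


# ---------------------------------------------------------------------------
# truth-table I/O: BED6+ (0-based half-open) and a JSON twin


def write_truth_bed(truths: list[TruthRecord], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, t in enumerate(truths):
            carriers = ",".join(str(h) for h in sorted(t.carrier_haplotypes))
            fh.write(
                "\t".join(
                    [
                        t.contig,
                        str(t.position),
                        str(t.position + t.tsd_length),
                        f"truth_{i}",
                        "0",
                        t.strand,
                        t.family,
                        str(t.tsd_length),
                        carriers,
                        f"{t.true_taf:.6g}",
                    ]
                )
                + "\n"
            )
    return path


def write_truth_json(truths: list[TruthRecord], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([t.to_dict() for t in truths], indent=1))
    return path


def read_truth_json(path) -> list[TruthRecord]:
    records = json.loads(Path(path).read_text())
    return [
        TruthRecord(
            contig=d["contig"],
            position=d["position"],
            family=d["family"],
            strand=d["strand"],
            tsd_length=d["tsd_length"],
            carrier_haplotypes=frozenset(d["carrier_haplotypes"]),
            true_taf=d["true_taf"],
            true_allele_copy_number=d["true_allele_copy_number"],
        )
        for d in records
    ]


# ---------------------------------------------------------------------------
# TE lineage evolution for the phylogenetics module


def evolve_te_lineages(
    canonical: str,
    tree_spec: str,
    subs_per_site: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, str], str]:
    """Simulate sequences along a rooted newick topology under a
    Jukes-Cantor substitution process.

    Branch lengths scaled by ``subs_per_site`` give expected
    substitutions per site on each branch; a site differs across a branch
    of scaled length t with probability (3/4)(1 - exp(-4t/3)), and a
    changed site takes each of the other three bases equally.  Returns
    leaf name -> sequence plus the true tree (the input newick).
    """
    from skbio import TreeNode

    if subs_per_site < 0:
        raise ValueError("subs_per_site must be >= 0")
    tree = TreeNode.read(StringIO(tree_spec))
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            raise ValueError(
                f"non-positive branch length on node {node.name!r}"
            )
    rng = np.random.default_rng(seed)
    leaves: dict[str, str] = {}

    def descend(node, codes: np.ndarray) -> None:
        for child in node.children:
            t = child.length * subs_per_site
            p_diff = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
            mask = rng.random(len(codes)) < p_diff
            child_codes = codes.copy()
            idx = np.flatnonzero(mask)
            child_codes[idx] = (child_codes[idx] + rng.integers(1, 4, idx.size)) % 4
            if child.is_tip():
                leaves[child.name] = to_str(child_codes)
            else:
                descend(child, child_codes)

    descend(tree, to_codes(canonical))
    return leaves, tree_spec


def expansion_fixture(
    n_sources: int,
    seed: int = 0,
    n_cellline: int = 5,
    n_outgroup_per_side: int = 3,
    canonical_length: int = 800,
    shallow: float = 0.005,
    stem: float = 0.02,
    side: float = 0.03,
    outgroup_tip: float = 0.02,
    cellline_sample: str = "cellline",
) -> tuple[dict[str, str], str, dict[str, tuple[str, int]]]:
    """Simulate a TE family expanded from 1 or 2 source lineages.

    Builds a two-sided topology whose deep central split separates the
    source clades; cell-line leaves carry allele copy number 1 (new
    haplotype-specific insertions), outgroup leaves represent older
    insertions from other samples.  Returns (leaf sequences, true newick,
    per-leaf metadata of (sample, allele copy number)).
    """
    if n_sources not in (1, 2):
        raise ValueError("n_sources must be 1 or 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    canonical = to_str(_random_codes(canonical_length, rng, 20))

    metadata: dict[str, tuple[str, int]] = {}
    out_idx = [0]

    def clade(tag: str, n: int) -> str:
        names = [f"{tag}{j}" for j in range(n)]
        for nm in names:
            metadata[nm] = (cellline_sample, 1)
        inner = ",".join(f"{nm}:{shallow}" for nm in names)
        return f"({inner}):{stem}"

    def outgroups(n: int) -> list[str]:
        parts = []
        for _ in range(n):
            nm = f"o{out_idx[0]}"
            out_idx[0] += 1
            metadata[nm] = ("strain", 2)
            parts.append(f"{nm}:{outgroup_tip}")
        return parts

    side_a = ",".join([clade("a", n_cellline)] + outgroups(n_outgroup_per_side))
    parts_b = outgroups(n_outgroup_per_side)
    if n_sources == 2:
        parts_b = [clade("b", n_cellline)] + parts_b
    side_b = ",".join(parts_b)
    newick = f"(({side_a}):{side},({side_b}):{side});"

    leaves, _ = evolve_te_lineages(canonical, newick, subs_per_site=1.0,
                                   seed=int(rng.integers(2**31)))
    return leaves, newick, metadata
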