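"""Phylogenetics contracts: full-length filtering, alignment, trimming,
tree building and expansion-clade classification."""

from __future__ import annotations

import numpy as np
import pytest

import longte.phylo as ph
import longte.simulate as sim
from longte.quantify import TECall
from longte.seqs import to_str
from longte.simulate import _random_codes


def make_call(family, te_len, contig="chr2L", start=1_000_000, taf=0.5,
              status="resolved", ident="c"):
    return TECall(
        id=ident, contig=contig, start=start, end=start + 4, family=family,
        strand="+", tsd_sequence=None, tsd_length=4, status=status,
        te_sequence="A" * te_len, support_count=10, taf=taf, raw_taf=taf,
    )


class TestFilterFullLength:
    def test_family_specific_ratio_bounds(self, te_library):
        len_297 = te_library.canonical_length("297")
        len_copia = te_library.canonical_length("copia")
        calls = [
            make_call("297", int(0.80 * len_297), ident="a"),
            make_call("copia", int(0.80 * len_copia), ident="b"),
            make_call("copia", len_copia, ident="c"),
        ]
        kept, reasons = ph.filter_full_length(calls, te_library)
        ids = [i for fam in kept.values() for i, _ in fam]
        assert "a" in ids       # 297 uses the relaxed 0.75-1.05 window
        assert "b" not in ids   # other families use 0.95-1.05
        assert "c" in ids
        assert reasons["length_ratio"] == 1

    def test_taf_and_flank_requirements(self, te_library):
        n = te_library.canonical_length("copia")
        calls = [
            make_call("copia", n, taf=None, ident="no_taf"),
            make_call("copia", n, status="gap_exceeded", ident="unres"),
            make_call("copia", n, ident="good"),
        ]
        kept, reasons = ph.filter_full_length(calls, te_library)
        ids = [i for fam in kept.values() for i, _ in fam]
        assert ids == ["good"]
        assert reasons["no_taf"] == 1 and reasons["flanks_unmapped"] == 1

    def test_region_mask_and_exclusions(self, te_library):
        n = te_library.canonical_length("copia")
        cfg = ph.FullLengthFilterConfig(
            region_mask={"chr2L": [(200_000, 20_100_000)]},
            exclude_contigs=("chrX",),
        )
        calls = [
            make_call("copia", n, contig="chrX", ident="x"),
            make_call("copia", n, contig="chr2L", start=100, ident="low"),
            make_call("copia", n, contig="chr2L", start=500_000, ident="ok"),
            make_call("unknownfam", n, contig="chr2L", start=600_000, ident="uf"),
        ]
        kept, reasons = ph.filter_full_length(calls, te_library, cfg)
        ids = [i for fam in kept.values() for i, _ in fam]
        assert ids == ["ok"]
        assert reasons["excluded_contig"] == 1
        assert reasons["outside_region_mask"] == 1
        assert reasons["unknown_family"] == 1

    def test_tightening_bounds_shrinks_retained_set(self, te_library):
        n = te_library.canonical_length("copia")
        calls = [make_call("copia", n + d, ident=f"c{d}") for d in (-100, 0, 100)]
        loose, _ = ph.filter_full_length(
            calls, te_library, ph.FullLengthFilterConfig(default_bounds=(0.9, 1.1)))
        tight, _ = ph.filter_full_length(
            calls, te_library, ph.FullLengthFilterConfig(default_bounds=(0.99, 1.01)))
        loose_ids = {i for fam in loose.values() for i, _ in fam}
        tight_ids = {i for fam in tight.values() for i, _ in fam}
        assert tight_ids <= loose_ids


class TestBuildFamilyAlignment:
    def test_identical_sequences_align_gap_free(self):
        seq = sim.make_reference(10_000, 1)[:500]
        msa = ph.build_family_alignment([("a", seq), ("b", seq), ("c", seq)],
                                        engine="builtin")
        assert all(row == seq for _, row in msa)

    def test_deletion_becomes_gap_block(self):
        seq = sim.make_reference(10_000, 2)[:500]
        deleted = seq[:200] + seq[210:]
        msa = ph.build_family_alignment(
            [("a", seq), ("b", seq), ("c", deleted)], engine="builtin")
        rows = dict(msa)
        assert len(set(len(r) for r in rows.values())) == 1
        # ten gap columns, all at the deleted region (edit-equivalent
        # placements may split the block)
        gap_cols = [i for i, ch in enumerate(rows["c"]) if ch == "-"]
        assert len(gap_cols) == 10
        assert all(195 <= i < 220 for i in gap_cols)
        assert rows["a"] == seq

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            ph.build_family_alignment([("a", "ACGT"), ("b", "ACGT")])

    @pytest.mark.skipif(not ph._mafft_available(), reason="mafft not on PATH")
    def test_mafft_engine_round_trips_rows(self):
        seq = sim.make_reference(10_000, 3)[:400]
        msa = ph.build_family_alignment(
            [("a", seq), ("b", seq[:150] + seq[160:]), ("c", seq)],
            engine="mafft")
        assert {name for name, _ in msa} == {"a", "b", "c"}
        assert len({len(row) for _, row in msa}) == 1


def overlap_score_oracle(msa, resoverlap, seqoverlap):
    """Direct, loop-based computation of the trimming rule."""
    kept = []
    n = len(msa)
    for i, (name, row) in enumerate(msa):
        good = total = 0
        for c, ch in enumerate(row):
            if ch == "-":
                continue
            total += 1
            same = sum(1 for j in range(n) if j != i and msa[j][1][c] == ch)
            if same / (n - 1) >= resoverlap:
                good += 1
        if total and 100.0 * good / total >= seqoverlap:
            kept.append(name)
    return kept


class TestTrimAlignment:
    @pytest.fixture(scope="class")
    def msa_with_outlier(self):
        rng = np.random.default_rng(5)
        seq = to_str(_random_codes(400, rng, 20))
        rows = [(f"s{i}", seq) for i in range(9)]
        rows.append(("outlier", to_str(_random_codes(400, rng, 20))))
        return rows

    def test_identical_rows_all_kept(self):
        msa = [(f"s{i}", "ACGTACGT") for i in range(10)]
        kept, removed = ph.trim_alignment(msa)
        assert len(kept) == 10 and not removed

    def test_random_row_removed(self, msa_with_outlier):
        kept, removed = ph.trim_alignment(msa_with_outlier)
        assert removed == ["outlier"]
        assert len(kept) == 9

    def test_matches_direct_overlap_computation(self, msa_with_outlier):
        for resoverlap, seqoverlap in ((0.75, 80.0), (0.5, 50.0), (0.9, 95.0)):
            oracle = overlap_score_oracle(msa_with_outlier, resoverlap, seqoverlap)
            if not oracle:
                with pytest.raises(ValueError):
                    ph.trim_alignment(msa_with_outlier, resoverlap, seqoverlap)
                continue
            kept, _ = ph.trim_alignment(msa_with_outlier, resoverlap, seqoverlap)
            assert [name for name, _ in kept] == oracle

    def test_zero_resoverlap_keeps_everything(self, msa_with_outlier):
        kept, removed = ph.trim_alignment(msa_with_outlier, resoverlap=0.0)
        assert len(kept) == 10 and not removed

    def test_idempotent(self, msa_with_outlier):
        once, _ = ph.trim_alignment(msa_with_outlier)
        twice, removed = ph.trim_alignment(once)
        assert twice == once and not removed

    def test_all_removed_is_an_error(self):
        rng = np.random.default_rng(6)
        msa = [(f"s{i}", to_str(_random_codes(200, rng, 20))) for i in range(4)]
        with pytest.raises(ValueError, match="unusable"):
            ph.trim_alignment(msa, resoverlap=1.0, seqoverlap=100.0)


class TestBuildTree:
    def test_deep_split_recovered_with_high_support(self):
        leaves, _, _ = sim.expansion_fixture(2, seed=1)
        msa = [(n, s) for n, s in leaves.items()]
        result = ph.build_tree(msa, bootstrap_replicates=100, seed=1)
        a_side = frozenset(n for n in leaves if n.startswith("a"))
        taxa = frozenset(leaves)
        ref = min(leaves)
        key = a_side if ref not in a_side else taxa - a_side
        assert result.supports.get(key, 0) >= 95

    def test_identical_rows_flag_star_tree(self):
        msa = [(f"s{i}", "ACGT" * 50) for i in range(5)]
        result = ph.build_tree(msa)
        assert result.star and not result.supports

    def test_three_rows_no_supports(self):
        seq = sim.make_reference(10_000, 4)[:300]
        msa = [("a", seq), ("b", seq[:100] + "T" + seq[101:]), ("c", seq)]
        result = ph.build_tree(msa)
        assert result.supports == {}

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ph.build_tree([("a", "ACGT"), ("b", "ACGT")])


def tree_result_from_newick(newick, supports_pct):
    """A TreeResult with hand-assigned bipartition supports keyed the
    same way build_tree keys them."""
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    ids = sorted(t.name for t in tree.tips())
    taxa = frozenset(ids)
    ref = min(ids)
    supports = {}
    for members, pct in supports_pct.items():
        key = frozenset(members)
        if ref in key:
            key = taxa - key
        supports[key] = pct
    return ph.TreeResult(tree=tree, supports=supports, ids=ids)


class TestClassifyExpansions:
    def test_qualifying_clade_detected(self):
        tr = tree_result_from_newick(
            "((c1:0.01,c2:0.01,c3:0.01,c4:0.01):0.2,(o1:0.1,o2:0.1):0.2);",
            {("c1", "c2", "c3", "c4"): 90.0},
        )
        meta = {f"c{i}": ("cellline", 1) for i in range(1, 5)}
        meta.update({"o1": ("strain", 2), "o2": ("strain", 2)})
        clades = ph.classify_expansions(tr, meta)
        assert len(clades) == 1
        c = clades[0]
        assert c.n_copy_number_one_cellline == 4
        assert c.prop_cn1 == 1.0 and c.bootstrap == 90.0

    def test_too_few_insertions_rejected(self):
        tr = tree_result_from_newick(
            "((c1:0.01,c2:0.01):0.2,(o1:0.1,o2:0.1):0.2);",
            {("c1", "c2"): 99.0},
        )
        meta = {"c1": ("cellline", 1), "c2": ("cellline", 1),
                "o1": ("strain", 2), "o2": ("strain", 2)}
        assert ph.classify_expansions(tr, meta) == []

    def test_low_proportion_rejected(self):
        inner = ",".join(f"o{i}:0.05" for i in range(17))
        tr = tree_result_from_newick(
            f"((c1:0.01,c2:0.01,c3:0.01,{inner}):0.2,(x1:0.1,x2:0.1):0.2);",
            {tuple([f"c{i}" for i in range(1, 4)] + [f"o{i}" for i in range(17)]): 99.0},
        )
        meta = {f"c{i}": ("cellline", 1) for i in range(1, 4)}
        meta.update({f"o{i}": ("strain", 2) for i in range(17)})
        meta.update({"x1": ("strain", 2), "x2": ("strain", 2)})
        # 3 of 20 members -> prop 0.15 < 0.2
        assert ph.classify_expansions(tr, meta) == []

    def test_low_bootstrap_rejected(self):
        tr = tree_result_from_newick(
            "((c1:0.01,c2:0.01,c3:0.01,c4:0.01):0.2,(o1:0.1,o2:0.1):0.2);",
            {("c1", "c2", "c3", "c4"): 40.0},
        )
        meta = {f"c{i}": ("cellline", 1) for i in range(1, 5)}
        meta.update({"o1": ("strain", 2), "o2": ("strain", 2)})
        assert ph.classify_expansions(tr, meta) == []

    def test_missing_metadata_names_leaf(self):
        tr = tree_result_from_newick(
            "((c1:0.01,c2:0.01,c3:0.01):0.2,(o1:0.1,o2:0.1):0.2);", {})
        meta = {"c1": ("cellline", 1), "c2": ("cellline", 1),
                "c3": ("cellline", 1), "o1": ("strain", 2)}
        with pytest.raises(ValueError, match="o2"):
            ph.classify_expansions(tr, meta)

    @pytest.mark.parametrize("n_sources", [1, 2])
    def test_source_lineage_count_recovered(self, n_sources):
        leaves, _, meta = sim.expansion_fixture(n_sources, seed=7)
        msa = ph.build_family_alignment(list(leaves.items()), engine="builtin")
        msa, _ = ph.trim_alignment(msa)
        tree = ph.build_tree(msa, bootstrap_replicates=100, seed=7)
        clades = ph.classify_expansions(tree, meta)
        assert len(clades) == n_sources
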