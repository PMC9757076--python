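"""Stage 2-3 contracts: support-read collection, consensus polishing,
TE annotation on contigs, flank mapping and TSD/breakpoint resolution."""

from __future__ import annotations

import numpy as np
import pytest

import longte.assemble as asm
import longte.simulate as sim
from longte.detect import InsertionCandidate
from longte.seqs import revcomp, to_str, write_fasta
from longte.simulate import _random_codes


def flank_mapping(start, end, strand="+", qlen=None, qstart=0, qend=None,
                  contig="chr1"):
    qlen = qlen if qlen is not None else end - start
    qend = qend if qend is not None else qlen
    return asm.FlankMapping(contig=contig, start=start, end=end, strand=strand,
                            query_length=qlen, query_start=qstart, query_end=qend)


class TestResolveBreakpoint:
    def test_overlap_defines_tsd(self, clean_sim):
        ref = {sim.REFERENCE_NAME: clean_sim.reference}
        f5 = flank_mapping(8_000, 10_004, contig=sim.REFERENCE_NAME)
        f3 = flank_mapping(10_000, 12_000, contig=sim.REFERENCE_NAME)
        r = asm.resolve_breakpoint(f5, f3, reference=ref)
        assert r.status == asm.STATUS_RESOLVED
        assert (r.start, r.end) == (10_000, 10_004)
        assert r.tsd_length == 4
        assert r.tsd_sequence == clean_sim.reference[10_000:10_004]

    def test_abutting_flanks_no_tsd(self):
        r = asm.resolve_breakpoint(flank_mapping(8_000, 10_000),
                                   flank_mapping(10_000, 12_000))
        assert r.status == asm.STATUS_RESOLVED
        assert (r.start, r.end) == (10_000, 10_000)
        assert r.tsd_length == 0 and r.tsd_sequence is None

    def test_small_gap_defines_interval(self):
        r = asm.resolve_breakpoint(flank_mapping(8_000, 10_000),
                                   flank_mapping(10_015, 12_000))
        assert r.status == asm.STATUS_RESOLVED
        assert (r.start, r.end) == (10_000, 10_015)
        assert r.tsd_sequence is None

    def test_gap_beyond_threshold_not_resolved(self):
        r = asm.resolve_breakpoint(flank_mapping(8_000, 10_000),
                                   flank_mapping(10_030, 12_000),
                                   gap_threshold=20)
        assert r.status == asm.STATUS_GAP_EXCEEDED

    def test_overlap_beyond_threshold_not_resolved(self):
        r = asm.resolve_breakpoint(flank_mapping(8_000, 10_025),
                                   flank_mapping(10_000, 12_000),
                                   overlap_threshold=20)
        assert r.status == asm.STATUS_OVERLAP_EXCEEDED

    def test_inconsistent_flanks_rejected(self):
        with pytest.raises(ValueError):
            asm.resolve_breakpoint(flank_mapping(8_000, 10_000, contig="chr1"),
                                   flank_mapping(10_000, 12_000, contig="chr2"))
        with pytest.raises(ValueError):
            asm.resolve_breakpoint(flank_mapping(8_000, 10_000, strand="+"),
                                   flank_mapping(10_000, 12_000, strand="-"))

    def test_one_flank_only(self):
        r = asm.resolve_breakpoint(flank_mapping(8_000, 10_000), None)
        assert r.status == asm.STATUS_ONE_FLANK_ONLY


class TestPolishContig:
    def test_zero_rounds_is_identity(self):
        contig = sim.make_reference(10_000, 1)
        polished, rounds = asm.polish_contig(contig, {}, rounds=0)
        assert polished == contig and rounds == 0

    def test_majority_vote_corrects_backbone_substitution(self):
        truth = sim.make_reference(10_000, 2)
        backbone = truth[:5_000] + ("A" if truth[5_000] != "A" else "C") + truth[5_001:]
        reads = {f"r{i}": truth for i in range(20)}
        polished, rounds = asm.polish_contig(backbone, reads, rounds=1)
        assert rounds == 1
        assert polished == truth

    def test_consensus_fixes_noisy_backbone(self):
        rng = np.random.default_rng(3)
        truth = sim.make_reference(10_000, 3)
        noisy = to_str(sim._mutate(sim.to_codes(truth), rng, 0.08,
                                   (0.6, 0.2, 0.2)))
        reads = {
            f"r{i}": to_str(sim._mutate(sim.to_codes(truth), rng, 0.08,
                                        (0.6, 0.2, 0.2)))
            for i in range(30)
        }
        polished, _ = asm.polish_contig(noisy, reads, rounds=2)
        import edlib

        identity = 1 - edlib.align(polished, truth)["editDistance"] / len(truth)
        assert identity >= 0.99


class TestAnnotateTEInterval:
    @pytest.fixture(scope="class")
    def flanks(self):
        rng = np.random.default_rng(11)
        return (to_str(_random_codes(1_500, rng, 20)),
                to_str(_random_codes(1_500, rng, 20)))

    def test_exact_interval_forward(self, te_library, flanks):
        left, right = flanks
        te = te_library["copia"].sequence
        contig = left + te + right
        (s, e), family, strand = asm.annotate_te_interval(contig, te_library)
        assert family == "copia" and strand == "+"
        assert (s, e) == (len(left), len(left) + len(te))

    def test_reverse_complement_flips_strand(self, te_library, flanks):
        left, right = flanks
        te = revcomp(te_library["copia"].sequence)
        contig = left + te + right
        (s, e), family, strand = asm.annotate_te_interval(contig, te_library)
        assert family == "copia" and strand == "-"
        assert (s, e) == (len(left), len(left) + len(te))

    def test_truncated_te_covers_retained_portion(self, te_library, flanks):
        left, right = flanks
        te = te_library["copia"].sequence
        retained = te[int(0.4 * len(te)):]  # 5' truncated by 40%
        contig = left + retained + right
        (s, e), family, _ = asm.annotate_te_interval(contig, te_library)
        assert family == "copia"
        assert abs((e - s) - len(retained)) < 50

    def test_no_hit_returns_none(self, te_library, flanks):
        rng = np.random.default_rng(12)
        contig = to_str(_random_codes(6_000, rng, 20))
        assert asm.annotate_te_interval(contig, te_library) is None

    def test_short_contig_rejected(self, te_library):
        with pytest.raises(ValueError, match="too short"):
            asm.annotate_te_interval("ACGT" * 100, te_library)


class TestFlankMappingAndInvolution:
    @pytest.fixture(scope="class")
    def planted(self, clean_sim, te_library, tmp_path_factory):
        """An error-free contig built at a known reference site."""
        ref = clean_sim.reference
        p, tsd = 50_000, 5
        te = te_library["roo"].sequence
        contig = ref[p - 1_500 : p + tsd] + te + ref[p : p + 1_500]
        te_interval = (1_500 + tsd, 1_500 + tsd + len(te))
        return {"contig": contig, "te_interval": te_interval, "p": p, "tsd": tsd}

    def test_flanks_map_to_planted_locus(self, planted, clean_sim):
        s, e = planted["te_interval"]
        f5, f3 = asm.map_flanks(planted["contig"][:s], planted["contig"][e:],
                                clean_sim.reference_fa)
        r = asm.resolve_breakpoint(f5, f3, reference={
            sim.REFERENCE_NAME: clean_sim.reference})
        assert r.status == asm.STATUS_RESOLVED
        assert (r.start, r.end) == (planted["p"], planted["p"] + planted["tsd"])
        assert r.tsd_sequence == clean_sim.reference[
            planted["p"] : planted["p"] + planted["tsd"]]

    def test_strand_involution(self, planted, clean_sim):
        """Reverse-complementing the contig swaps flank roles but leaves
        the breakpoint resolution unchanged."""
        s, e = planted["te_interval"]
        contig_rc = revcomp(planted["contig"])
        L = len(planted["contig"])
        rc_te = (L - e, L - s)
        f5, f3 = asm.map_flanks(contig_rc[: rc_te[0]], contig_rc[rc_te[1]:],
                                clean_sim.reference_fa)
        r = asm.resolve_breakpoint(f5, f3, reference={
            sim.REFERENCE_NAME: clean_sim.reference})
        assert r.status == asm.STATUS_RESOLVED
        assert (r.start, r.end) == (planted["p"], planted["p"] + planted["tsd"])

    def test_duplicated_flank_is_ambiguous(self, clean_sim, tmp_path):
        # reference with the flank region copied elsewhere
        ref = clean_sim.reference
        dup_ref = ref + ref[49_000:51_000]
        ref_fa = write_fasta(tmp_path / "dup_ref.fa",
                             [(sim.REFERENCE_NAME, dup_ref)])
        f5, f3 = asm.map_flanks(ref[49_000:50_000], ref[50_000:51_000], ref_fa)
        assert f5 is not None and f5.ambiguous
        assert f3 is not None and f3.ambiguous


class TestCollectSupportReads:
    def test_named_reads_returned(self):
        cand = InsertionCandidate("c", "chr1", 100, "ACGT", {"a", "b"})
        reads = {"a": "AAAA", "b": "CCCC", "c": "GGGG"}
        assert asm.collect_support_reads(cand, reads) == {"a": "AAAA", "b": "CCCC"}

    def test_missing_names_warned_but_returned(self, caplog):
        cand = InsertionCandidate("c", "chr1", 100, "ACGT", {"a", "zz"})
        with caplog.at_level("WARNING", logger="longte.assemble"):
            out = asm.collect_support_reads(cand, {"a": "AAAA"})
        assert out == {"a": "AAAA"}
        assert any("absent" in r.message for r in caplog.records)

    def test_single_read_assembly_rejected(self, clean_sim):
        cand = InsertionCandidate("c", sim.REFERENCE_NAME, 50_000, "ACGT", {"a"})
        with pytest.raises(asm.AssemblyError, match="supporting reads"):
            asm.assemble_local_contig({"a": "ACGT" * 1000}, cand,
                                      {sim.REFERENCE_NAME: clean_sim.reference})
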