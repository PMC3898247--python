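"""Pileup oracle equivalence and the C->U edit-site filters."""

import numpy as np
import pytest

import mtscope as m
from mtscope import editing

from conftest import make_genome, write_sam


class TestBuildPileup:
    def test_all_matching_reads(self, tmp_path):
        g = make_genome("C" * 200)
        sam = tmp_path / "r.sam"
        write_sam(sam, g, [(f"r{i}", 0, 50, "20M", "C" * 20) for i in range(10)])
        pile = m.build_pileup(sam, g)
        col = pile.column(60)
        assert col.depth == 10 and col.counts == {"A": 0, "C": 10, "G": 0, "T": 0}

    def test_mixed_column_counts(self, tmp_path):
        g = make_genome("C" * 200)
        sam = tmp_path / "r.sam"
        reads = [(f"r{i}", 0, 50, "20M", "C" * 20) for i in range(6)]
        reads += [(f"t{i}", 0, 50, "20M", "C" * 10 + "T" + "C" * 9) for i in range(4)]
        write_sam(sam, g, reads)
        col = m.build_pileup(sam, g).column(60)
        assert col.counts["C"] == 6 and col.counts["T"] == 4 and col.depth == 10

    def test_ambiguous_bases_drop_from_counts_not_depth(self, tmp_path):
        g = make_genome("C" * 100)
        sam = tmp_path / "r.sam"
        write_sam(sam, g, [("r1", 0, 10, "5M", "CCNCC")])
        pile = m.build_pileup(sam, g)
        col = pile.column(12)
        assert col.depth == 1 and sum(col.counts.values()) == 0

    def test_matches_per_read_rewalk_oracle(self, tmp_path):
        """Independent re-walk of every read string, wrap-around included."""
        rng = np.random.default_rng(11)
        L = 1500
        g = make_genome("".join(rng.choice(list("ACGT"), L)))
        base_idx = {b: i for i, b in enumerate("ACGT")}
        reads = []
        counts = np.zeros((L, 4), dtype=int)
        depth = np.zeros(L, dtype=int)
        for i in range(800):
            start = int(rng.integers(0, L))
            ln = int(rng.integers(20, 80))
            seq = list(g.fetch(start, start + ln))
            # sprinkle mismatches
            for _ in range(int(rng.integers(0, 3))):
                k = int(rng.integers(0, ln))
                seq[k] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(seq)
            if start + ln <= L:
                reads.append((f"r{i}", 0, start, f"{ln}M", seq))
            else:
                head = L - start
                reads.append((f"r{i}", 0, start, f"{head}M{ln - head}S", seq))
                reads.append((f"r{i}", 2048, 0, f"{head}S{ln - head}M", seq))
            for k, b in enumerate(seq):
                p = (start + k) % L
                depth[p] += 1
                counts[p, base_idx[b]] += 1
        sam = tmp_path / "r.sam"
        write_sam(sam, g, reads)
        pile = m.build_pileup(sam, g)
        assert (pile.depth == depth).all()
        assert (pile.counts == counts).all()


def _pileup_with_column(ref_base, depth, edited, matching, pos=50):
    """Hand-built single-column pileup."""
    g = make_genome("A" * 40 + ref_base * 30 + "A" * 30)
    pile = editing.Pileup(g)
    e_idx = {"C": editing._BASE_INDEX["T"], "G": editing._BASE_INDEX["A"]}[ref_base]
    m_idx = editing._BASE_INDEX[ref_base]
    pile.depth[pos] = depth
    pile.counts[pos, e_idx] = edited
    pile.counts[pos, m_idx] = matching
    return pile


class TestCallSites:
    def test_edit_call_arithmetic(self):
        pile = _pileup_with_column("C", 250, edited=100, matching=150)
        (s,) = m.call_sites(pile)
        assert s.call_class == editing.CLASS_EDIT
        assert s.edit_fraction == pytest.approx(0.40)
        assert s.orientation == editing.ORIENT_FORWARD

    def test_full_substitution_is_snp(self):
        pile = _pileup_with_column("C", 250, edited=250, matching=0)
        (s,) = m.call_sites(pile)
        assert s.call_class == editing.CLASS_SNP

    def test_depth_threshold_is_strict(self):
        pile = _pileup_with_column("C", 150, edited=60, matching=90)
        (s,) = m.call_sites(pile)
        assert s.call_class == editing.CLASS_SUBTHRESHOLD_DEPTH
        pile = _pileup_with_column("C", 200, edited=60, matching=140)
        (s,) = m.call_sites(pile)
        assert s.call_class == editing.CLASS_SUBTHRESHOLD_DEPTH

    def test_low_fraction_and_low_count(self):
        pile = _pileup_with_column("C", 1000, edited=3, matching=997)
        (s,) = m.call_sites(pile)
        assert s.call_class == editing.CLASS_SUBTHRESHOLD_FRACTION

    def test_reverse_orientation_g_to_a(self):
        pile = _pileup_with_column("G", 300, edited=120, matching=180)
        (s,) = m.call_sites(pile)
        assert s.orientation == editing.ORIENT_REVERSE
        assert s.call_class == editing.CLASS_EDIT

    def test_non_cu_mismatches_never_call(self, tmp_path):
        g = make_genome("A" * 100)
        sam = tmp_path / "r.sam"
        write_sam(sam, g, [(f"r{i}", 0, 10, "10M", "AAAAGAAAAA") for i in range(300)])
        pile = m.build_pileup(sam, g)
        assert m.call_sites(pile) == []

    def test_snp_tolerance_absorbs_sequencing_error(self, tmp_path):
        """A 100% SNP plus error stays a SNP once tolerance >= 3*error."""
        cfg = m.default_config(seed=3, error_rate=0.002)
        res = m.simulate_dataset(cfg, tmp_path)
        pile = m.build_pileup(res["sam"], res["genome"])
        snp_pos = {s.pos for s in cfg.snp_plan}
        strict = {
            s.pos
            for s in m.call_sites(pile, snp_tolerance=3 * 0.002)
            if s.call_class == editing.CLASS_EDIT
        }
        assert not (snp_pos & strict)


class TestPlantedTruthRecovery:
    def test_full_sensitivity_and_snp_rejection(self, default_sim, default_tracks):
        """Error-free defaults: every planted edit called, no SNP leaks in."""
        cfg = default_sim["config"]
        sites = m.call_sites(default_tracks["pileup"])
        edits = {s.pos for s in sites if s.call_class == editing.CLASS_EDIT}
        truth = {e.pos for e in cfg.edit_plan}
        assert truth <= edits
        snps = {s.pos for s in cfg.snp_plan}
        assert not (snps & edits)
        assert all(
            s.depth > 200 for s in sites if s.call_class == editing.CLASS_EDIT
        )

    def test_calls_bit_exactly_reproducible(self, default_sim, default_tracks):
        a = m.call_sites(default_tracks["pileup"])
        b = m.call_sites(default_tracks["pileup"])
        assert a == b


class TestDiagnoseMissed:
    def test_reasons(self, tmp_path):
        g = make_genome("C" * 400)
        sam = tmp_path / "r.sam"
        reads = []
        # pos 100: depth 80 with a 50% edit fraction -> low_depth
        reads += [(f"a{i}", 0, 90, "20M", "C" * 10 + "T" + "C" * 9) for i in range(40)]
        reads += [(f"e{i}", 0, 90, "20M", "C" * 20) for i in range(40)]
        # pos 200: deep but fraction 1% -> low_fraction
        reads += [(f"b{i}", 0, 190, "20M", "C" * 20) for i in range(990)]
        reads += [(f"c{i}", 0, 190, "20M", "C" * 10 + "T" + "C" * 9) for i in range(10)]
        # pos 300: deep, no T at all -> no_mismatch_observed
        reads += [(f"d{i}", 0, 290, "20M", "C" * 20) for i in range(300)]
        write_sam(sam, g, reads)
        pile = m.build_pileup(sam, g)
        called = m.call_sites(pile)
        reasons = m.diagnose_missed(called, [100, 200, 300], pile)
        assert reasons[100] == editing.REASON_LOW_DEPTH
        assert reasons[200] == editing.REASON_LOW_FRACTION
        assert reasons[300] == editing.REASON_NO_MISMATCH

    def test_invalid_reference_flagged(self, tmp_path):
        g = make_genome("A" * 100)
        sam = tmp_path / "r.sam"
        write_sam(sam, g, [("r1", 0, 10, "10M", "A" * 10)])
        pile = m.build_pileup(sam, g)
        reasons = m.diagnose_missed([], [12], pile)
        assert reasons[12] == editing.REASON_INVALID_REF
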