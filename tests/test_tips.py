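import numpy as np
import pytest
from Bio.Seq import Seq

from slrkit import tips
from slrkit.regions import RegionMap
from slrkit.tips import (AlignmentBlock, IndelCandidate, align_pair, call_indels,
                         classify_te, filter_candidates, one_to_one, tip_summary)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(123)


class TestAlignPair:
    def test_identical_sequences_one_full_block(self, rng):
        s = _random_seq(rng, 10_000)
        blocks = align_pair(s, s)
        plus = [b for b in blocks if b.strand == "+"]
        assert len(plus) == 1
        b = plus[0]
        assert (b.ref_start, b.ref_end, b.qry_start, b.qry_end) == (0, 10_000, 0, 10_000)
        assert b.identity == 100.0

    def test_insertion_splits_into_two_collinear_blocks(self, rng):
        s = _random_seq(rng, 10_000)
        ins = _random_seq(rng, 60)
        q = s[:5000] + ins + s[5000:]
        blocks = [b for b in align_pair(s, q) if b.strand == "+"]
        assert len(blocks) == 2
        b1, b2 = sorted(blocks, key=lambda b: b.ref_start)
        g_ref = b2.ref_start - b1.ref_end
        g_qry = b2.qry_start - b1.qry_end
        assert g_qry - g_ref == 60

    def test_central_inversion_reported_on_minus_strand(self, rng):
        s = _random_seq(rng, 6_000)
        mid = str(Seq(s[2500:3500]).reverse_complement())
        q = s[:2500] + mid + s[3500:]
        blocks = align_pair(s, q)
        minus = [b for b in blocks if b.strand == "-"]
        assert len(minus) == 1
        b = minus[0]
        # oracle: exact string comparison of the reverse-complemented segment
        assert s[b.ref_start:b.ref_end] == str(
            Seq(q[b.qry_start:b.qry_end]).reverse_complement())
        assert 2450 <= b.ref_start <= 2500 and 3500 <= b.ref_end <= 3550

    def test_k_larger_than_sequence_errors(self):
        with pytest.raises(ValueError):
            align_pair("ACGT", "ACGT", anchor_k=21)


def _block(rs, re, qs, qe, ident=99.0, strand="+"):
    return AlignmentBlock("Y", "X", rs, re, qs, qe, strand, ident)


class TestOneToOne:
    def test_dominance_same_interval(self):
        blocks = [_block(0, 100, 0, 100, 95.0), _block(0, 100, 0, 100, 92.0)]
        kept = one_to_one(blocks)
        assert len(kept) == 1 and kept[0].identity == 95.0

    def test_identity_threshold(self):
        assert one_to_one([_block(0, 100, 0, 100, 85.0)]) == []

    def test_disjoint_blocks_all_kept(self):
        blocks = [_block(0, 100, 0, 100), _block(200, 300, 200, 300),
                  _block(400, 500, 400, 500)]
        assert one_to_one(blocks) == blocks

    def test_small_junction_overlap_is_trimmed(self):
        big = _block(0, 1000, 0, 1000)
        nxt = _block(999, 1500, 1050, 1551)  # 1-bp ref overlap with the big block
        kept = one_to_one([big, nxt])
        assert len(kept) == 2
        assert kept[1].ref_start == 1000 and kept[1].qry_start == 1051

    def test_no_overlap_invariant_on_random_blocks(self, rng):
        for _ in range(25):
            blocks = []
            for _ in range(15):
                rs = int(rng.integers(0, 500))
                qs = int(rng.integers(0, 500))
                length = int(rng.integers(30, 200))
                blocks.append(_block(rs, rs + length, qs, qs + length,
                                     float(rng.uniform(90, 100))))
            kept = one_to_one(blocks, max_trim=10)
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert min(a.ref_end, b.ref_end) <= max(a.ref_start, b.ref_start)
                    assert min(a.qry_end, b.qry_end) <= max(a.qry_start, b.qry_start)


class TestCallIndels:
    def test_planted_insertion_on_query(self, rng):
        s = _random_seq(rng, 10_000)
        ins = _random_seq(rng, 60)
        q = s[:5000] + ins + s[5000:]
        cands = call_indels(one_to_one(align_pair(s, q)), ref_seq=s, qry_seq=q)
        gaps = [c for c in cands if c.feature == "GAP"]
        assert len(gaps) == 1
        c = gaps[0]
        assert c.host == "X" and c.length == 60 and c.sequence == ins

    def test_short_insertion_below_min_len_not_called(self, rng):
        s = _random_seq(rng, 10_000)
        q = s[:5000] + _random_seq(rng, 49) + s[5000:]
        cands = call_indels(one_to_one(align_pair(s, q)), ref_seq=s, qry_seq=q)
        assert [c for c in cands if c.feature == "GAP"] == []

    def test_order_violation_flagged_brk(self):
        # the heavy collinear chain keeps the outer blocks; the transposed
        # middle block falls off the backbone and becomes a BRK candidate
        blocks = [_block(0, 1000, 0, 1000), _block(1100, 1300, 5000, 5200),
                  _block(1400, 2400, 1400, 2400)]
        cands = call_indels(blocks)
        assert any(c.feature == "BRK" and c.start == 1100 for c in cands)

    def test_unsorted_input_rejected(self):
        blocks = [_block(500, 600, 500, 600), _block(0, 100, 0, 100)]
        with pytest.raises(ValueError, match="sorted"):
            call_indels(blocks)

    def test_insertion_on_reference(self, rng):
        s = _random_seq(rng, 8_000)
        ins = _random_seq(rng, 120)
        ref = s[:4000] + ins + s[4000:]
        cands = call_indels(one_to_one(align_pair(ref, s)), ref_seq=ref, qry_seq=s)
        gaps = [c for c in cands if c.feature == "GAP"]
        assert len(gaps) == 1 and gaps[0].host == "Y" and gaps[0].sequence == ins


class TestFilterCandidates:
    def cand(self, start, end, host="X", feature="GAP"):
        return IndelCandidate(host=host, chrom="c", start=start, end=end,
                              sequence="A" * (end - start), feature=feature)

    def test_one_bp_gap_overlap_removed(self):
        out = filter_candidates([self.cand(100, 200)], gap_mask_x=[(199, 300)])
        assert out == []

    def test_adjacent_gap_kept_and_flagged_syntenic(self):
        out = filter_candidates([self.cand(100, 200)], gap_mask_x=[(200, 300)])
        assert len(out) == 1 and out[0].syntenic

    def test_brk_removed_and_empty_ok(self):
        assert filter_candidates([self.cand(0, 60, feature="BRK")]) == []
        assert filter_candidates([]) == []


@pytest.fixture(scope="module")
def lib():
    rng = np.random.default_rng(7)
    return [("LTR/Copia", _random_seq(rng, 300)), ("LTR/Gypsy", _random_seq(rng, 400))]


class TestClassifyTE:
    def cand(self, seq):
        return IndelCandidate(host="X", chrom="c", start=0, end=len(seq),
                              sequence=seq, feature="GAP")

    def test_exact_consensus_full_identity(self, lib):
        rec = classify_te(self.cand(lib[0][1]), lib)
        assert rec is not None
        assert (rec.family, rec.identity, rec.coverage) == ("LTR/Copia", 1.0, 1.0)

    def test_low_candidate_coverage_rejected(self, lib, rng):
        # a TE copy covering only ~70% of the candidate fails the 80% rule
        seq = lib[0][1] + _random_seq(rng, 130)
        assert classify_te(self.cand(seq), lib) is None

    def test_decision_matches_enumeration_oracle(self, lib):
        """For substitution-only mutants the optimal local alignment is
        ungapped, so exhaustive offset enumeration is an independent oracle
        for the accept/reject decision."""
        rng = np.random.default_rng(11)
        for rate in (0.05, 0.10, 0.15, 0.30):
            consensus = lib[1][1]
            seq = list(consensus)
            hits = rng.random(len(seq)) < rate
            for i in np.flatnonzero(hits):
                seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
            cand_seq = "".join(seq)
            # oracle: best ungapped identity over all offsets of both strands
            best = 0.0
            for oriented in (consensus, str(Seq(consensus).reverse_complement())):
                for off in range(-len(oriented) + 1, len(cand_seq)):
                    a = cand_seq[max(0, off):off + len(oriented)]
                    b = oriented[max(0, -off):max(0, -off) + len(a)]
                    if len(a) < 0.8 * len(cand_seq):
                        continue
                    ident = sum(x == y for x, y in zip(a, b)) / len(a)
                    best = max(best, ident)
            expected = best >= 0.8
            rec = classify_te(self.cand(cand_seq), lib)
            assert (rec is not None) == expected
            if rec:
                assert rec.family == "LTR/Gypsy"

    def test_threshold_monotonicity(self, lib):
        rng = np.random.default_rng(13)
        cands = []
        for _ in range(6):
            base = lib[rng.integers(0, 2)][1]
            seq = "".join(c if rng.random() > 0.15 else "A" for c in base)
            cands.append(self.cand(seq + _random_seq(rng, rng.integers(0, 60))))
        for tighter in ({"min_identity": 0.9}, {"min_coverage": 0.9}):
            loose = {c.start for c in cands if classify_te(c, lib)}
            tight = {c.start for c in cands if classify_te(c, lib, **tighter)}
            assert tight <= loose

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="library"):
            classify_te(self.cand("ACGT" * 30), [])


def test_swapping_inputs_swaps_sides(clean_pair):
    cfg, x, y, truth = clean_pair
    fwd = tips.detect_tips(y, x, truth.te_library, gap_mask_ref=truth.gap_intervals_y,
                           gap_mask_qry=truth.gap_intervals_x)
    rev = tips.detect_tips(x, y, truth.te_library, ref_host="X", qry_host="Y",
                           gap_mask_ref=truth.gap_intervals_x,
                           gap_mask_qry=truth.gap_intervals_y)
    fwd_counts = {s: sum(t.side == s for t in fwd) for s in ("X-TIP", "Y-TIP")}
    rev_counts = {s: sum(t.side == s for t in rev) for s in ("X-TIP", "Y-TIP")}
    assert fwd_counts["X-TIP"] == rev_counts["X-TIP"]
    assert fwd_counts["Y-TIP"] == rev_counts["Y-TIP"]
    assert sorted(t.start for t in fwd) == sorted(t.start for t in rev)


class TestTipSummary:
    def test_family_percentage_from_printed_counts(self):
        from slrkit.utils import percentage_table

        table = percentage_table({"LTR/Copia": 1571, "other": 2045})
        assert table.loc["LTR/Copia", "percent"] == 43.44

    def test_single_tip_median(self):
        rec = tips.TIPRecord("t1", "X-TIP", "c", 0, 898, "LTR/Copia", 1.0, 1.0)
        rmap = RegionMap.from_layout("c", [("PAR1", 1000)])
        summary = tip_summary([rec], {"X": rmap, "Y": rmap}, bin_size=500)
        assert summary.lengths.set_index("side").loc["X-TIP", "median"] == 898

    def test_density_contrast_detects_enrichment(self):
        rmap = RegionMap.from_layout("c", [("PAR1", 40_000), ("IV", 40_000)])
        records = []
        # 3x the planted rate inside the inversion vs the PAR
        for i, n_per_bin in enumerate([1] * 40 + [3] * 40):
            base = i * 1000
            for j in range(n_per_bin):
                start = base + 10 + j * 50
                records.append(tips.TIPRecord(f"t{i}_{j}", "Y-TIP", "c",
                                              start, start + 40, "LTR/Copia", 1.0, 1.0))
        summary = tip_summary(records, {"X": rmap, "Y": rmap}, bin_size=1000)
        t, p = summary.density_contrast
        assert p < 0.05 and t > 0
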