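"""CN-HMM: profile building, scanning, pairing, extraction."""

import math

import numpy as np
import pytest

from mycometer import rdna_hmm, simkit
from mycometer.rdna_hmm import HmmHit, PairingParams, count_copies


def _hit(contig, start, end, strand="+", score=100.0, e=1e-10):
    return HmmHit(contig, start, end, strand, score, e)


class TestBuildProfile:
    def test_identical_gapfree_alignment(self):
        rows = [("s%d" % i, "ACGT" * 25) for i in range(30)]
        prof = rdna_hmm.build_profile(rows)
        assert prof.M == 100
        # (30+1)/(30+4) for the observed base at every state
        assert np.allclose(prof.match_emissions.max(axis=1), 31 / 34)

    def test_majority_gap_column_excluded(self):
        rows = [("a", "A-CG"), ("b", "A-CG"), ("c", "AACG"),
                ("d", "A-CG"), ("e", "A-CG")]  # column 1 is 80% gaps
        prof = rdna_hmm.build_profile(rows)
        assert prof.M == 3

    def test_half_gap_column_excluded(self):
        rows = [("a", "A-G"), ("b", "ACG"), ("c", "A-G"), ("d", "ACG")]
        # column 1 is exactly 50% gaps: not < 50%, so excluded
        prof = rdna_hmm.build_profile(rows)
        assert prof.M == 2

    def test_emissions_equal_hand_pseudocounts(self):
        rows = [("a", "ACGTA"), ("b", "ACGTC"), ("c", "ATGTA")]
        prof = rdna_hmm.build_profile(rows)
        # column 0: 3 A -> (3+1)/(3+4); column 1: 2 C 1 T
        assert prof.match_emissions[0, 0] == pytest.approx(4 / 7)
        assert prof.match_emissions[1, 1] == pytest.approx(3 / 7)
        assert prof.match_emissions[1, 3] == pytest.approx(2 / 7)
        assert prof.match_emissions[1, 0] == pytest.approx(1 / 7)
        assert np.allclose(prof.match_emissions.sum(axis=1), 1.0)

    def test_transition_rows_are_probabilities(self):
        rows = [("a", "AC-TA"), ("b", "ACGTC"), ("c", "AT-TA"), ("d", "ACGTT")]
        prof = rdna_hmm.build_profile(rows)
        assert np.allclose(prof.t_mm + prof.t_mi + prof.t_md, 1.0)
        assert np.allclose(prof.t_im + prof.t_ii, 1.0)
        assert np.allclose(prof.t_dm + prof.t_dd, 1.0)

    def test_rejects_single_sequence_and_ragged(self):
        with pytest.raises(ValueError, match="2 sequences"):
            rdna_hmm.build_profile([("a", "ACGT")])
        with pytest.raises(ValueError, match="ragged"):
            rdna_hmm.build_profile([("a", "ACGT"), ("b", "ACG")])

    def test_stockholm_input(self, tmp_path, flank_templates):
        lsu_t, _ = flank_templates
        rows = simkit.flank_training_alignment(lsu_t[:60], 5, 0.02, seed=1)
        p = tmp_path / "aln.sto"
        with open(p, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for name, row in rows:
                fh.write(f"{name}  {row}\n")
            fh.write("//\n")
        prof = rdna_hmm.build_profile(p)
        assert prof.M == 60


class TestViterbiOracle:
    def test_kernel_equals_exhaustive_enumeration(self):
        """Best local-alignment score from the DP equals brute-force
        enumeration over every alignment of the same state space."""
        rng = np.random.default_rng(3)
        aln = simkit.flank_training_alignment(simkit.random_seq(rng, 6),
                                              n_seqs=4, divergence=0.3, seed=5)
        prof = rdna_hmm.build_profile(aln)
        M = prof.M
        entry = math.log2(1 / M)
        lg = np.log2
        tmm, tmi, tmd = lg(prof.t_mm), lg(prof.t_mi), lg(prof.t_md)
        tim, tii = lg(prof.t_im), lg(prof.t_ii)
        tdm, tdd = lg(prof.t_dm), lg(prof.t_dd)
        mllr = prof.match_llr

        def brute_best(codes):
            n = len(codes)
            best = -np.inf

            def rec(i, j, state, score):
                nonlocal best
                if state == "M":
                    best = max(best, score)
                if state == "M" and j < M - 1:
                    if i < n:
                        rec(i + 1, j + 1, "M", score + tmm[j] + mllr[j + 1, codes[i]])
                        rec(i + 1, j, "I", score + tmi[j])
                    rec(i, j + 1, "D", score + tmd[j])
                elif state == "I":
                    if i < n:
                        rec(i + 1, j, "I", score + tii[j])
                        if j < M - 1:
                            rec(i + 1, j + 1, "M", score + tim[j] + mllr[j + 1, codes[i]])
                elif state == "D" and j < M - 1:
                    rec(i, j + 1, "D", score + tdd[j])
                    if i < n:
                        rec(i + 1, j + 1, "M", score + tdm[j] + mllr[j + 1, codes[i]])

            for s0 in range(n):
                for j0 in range(M):
                    rec(s0 + 1, j0, "M", entry + mllr[j0, codes[s0]])
            return best

        for t in range(15):
            codes = simkit.encode(
                simkit.random_seq(np.random.default_rng(100 + t), 10)).astype(np.int64)
            scores, _ = prof.score_ends(codes)
            assert scores.max() == pytest.approx(brute_best(codes), abs=1e-9)


class TestScan:
    def test_planted_flank_interval_recovered_exactly(self, profiles,
                                                      make_genome):
        lsu_p, _ = profiles
        asm, truth = make_genome(1, divergence=0.0, seed=21)
        hits = rdna_hmm.scan_sequence(lsu_p, asm)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        loc = truth.loci[0]
        assert (plus[0].start, plus[0].end) == loc.lsu

    def test_reverse_complement_flank_found_on_minus_strand(self, profiles,
                                                            flank_templates):
        lsu_p, _ = profiles
        lsu_t, _ = flank_templates
        rng = np.random.default_rng(5)
        left, right = simkit.random_seq(rng, 3000), simkit.random_seq(rng, 3000)
        seq = left + simkit.revcomp(lsu_t) + right
        hits = rdna_hmm.scan_sequence(lsu_p, {"c": seq})
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert (minus[0].start, minus[0].end) == (3000, 3000 + len(lsu_t))

    def test_evalue_filter_controls_false_positives(self, profiles):
        """~100 random 100 kb sequences with no planted motif: at most one
        hit total at E <= 0.001 (expected false positives ~ e_max x trials)."""
        lsu_p, ssu_p = profiles
        total = 0
        for i in range(50):
            seq = simkit.random_seq(np.random.default_rng(9000 + i), 100_000)
            total += len(rdna_hmm.scan_sequence(lsu_p, {"r": seq}))
            total += len(rdna_hmm.scan_sequence(ssu_p, {"r": seq}))
        assert total <= 1

    def test_empty_profile_and_empty_assembly_error(self, profiles):
        lsu_p, _ = profiles
        with pytest.raises(ValueError, match="empty"):
            rdna_hmm.scan_sequence(lsu_p, {"c": ""})

    def test_hit_coordinates_half_open(self, profiles, make_genome):
        lsu_p, ssu_p = profiles
        asm, truth = make_genome(2, seed=22)
        for prof, key in ((lsu_p, "lsu"), (ssu_p, "ssu")):
            hits = rdna_hmm.scan_sequence(prof, asm)
            spans = {(h.start, h.end) for h in hits}
            expected = {getattr(l, key) for l in truth.loci}
            assert expected <= spans


class TestCountCopies:
    def test_tandem_array_with_canonical_gaps(self):
        # 5 planted pairs with 550 bp inner gaps -> 5 paired copies
        lsu = [_hit("c", 1000 + i * 3000, 1588 + i * 3000) for i in range(5)]
        ssu = [_hit("c", 2138 + i * 3000, 2280 + i * 3000) for i in range(5)]
        res = count_copies(lsu, ssu, {"c": 20_000})
        assert res.copy_number == 5
        assert all(l.completeness == "paired" for l in res.loci)
        assert all(l.end - l.start == 550 for l in res.loci)

    def test_gap_bounds_are_inclusive_exclusive_outside(self):
        lsu = [_hit("c", 1000, 1588), _hit("c", 10_000, 10_588)]
        ssu = [_hit("c", 1588 + 399, 1588 + 399 + 142),
               _hit("c", 10_588 + 801, 10_588 + 801 + 142)]
        assert count_copies(lsu, ssu, {"c": 50_000}).copy_number == 0
        ssu_in = [_hit("c", 1588 + 400, 1588 + 400 + 142),
                  _hit("c", 10_588 + 800, 10_588 + 800 + 142)]
        assert count_copies(lsu, ssu_in, {"c": 50_000}).copy_number == 2

    def test_contig_end_rule_counts_truncated_copy(self):
        res = count_copies([_hit("c", 49_000, 49_700)], [], {"c": 50_000})
        assert res.copy_number == 1
        assert res.loci[0].completeness == "end_truncated"

    def test_mid_contig_unpaired_hit_not_counted(self):
        res = count_copies([_hit("c", 10_000, 10_588)], [], {"c": 50_000})
        assert res.copy_number == 0

    def test_minus_strand_pairing(self):
        # on the minus strand the SSU sits at lower forward coordinates
        lsu = [_hit("c", 5000, 5588, "-")]
        ssu = [_hit("c", 4308, 4450, "-")]  # gap = 5000 - 4450 = 550
        res = count_copies(lsu, ssu, {"c": 20_000})
        assert res.copy_number == 1
        assert res.loci[0] == rdna_hmm.ITSLocus("c", 4450, 5000, "-", "paired")

    def test_unpaired_ssu_near_contig_start(self):
        res = count_copies([], [_hit("c", 200, 342)], {"c": 50_000})
        assert res.copy_number == 1
        assert res.loci[0].completeness == "end_truncated"

    def test_each_hit_used_once_and_nearest_wins(self):
        lsu = [_hit("c", 1000, 1588)]
        ssu = [_hit("c", 2100, 2242, score=10.0),  # gap 512
               _hit("c", 2300, 2442, score=99.0)]  # gap 712, better score
        res = count_copies(lsu, ssu, {"c": 50_000})
        assert res.copy_number == 1
        assert res.loci[0].end == 2100  # nearest gap wins regardless of score

    def test_overlapping_lsu_ssu_hits_discarded(self):
        lsu = [_hit("c", 1000, 1588)]
        ssu = [_hit("c", 1500, 1642)]
        with pytest.warns(UserWarning, match="overlap"):
            res = count_copies(lsu, ssu, {"c": 50_000})
        assert res.copy_number == 0

    def test_invalid_pairing_params(self):
        with pytest.raises(ValueError):
            PairingParams(min_gap=800, max_gap=400)


class TestEndToEnd:
    @pytest.mark.parametrize("K", [1, 2, 5, 20])
    def test_exact_recovery_zero_divergence(self, profiles, make_genome, K):
        lsu_p, ssu_p = profiles
        asm, truth = make_genome(K, divergence=0.0, seed=300 + K)
        res = rdna_hmm.cn_hmm_pipeline(asm, lsu_p, ssu_p)
        assert res.copy_number == K

    def test_strand_invariance(self, profiles, make_genome):
        lsu_p, ssu_p = profiles
        asm, _ = make_genome(3, divergence=0.02, seed=31)
        res_f = rdna_hmm.cn_hmm_pipeline(asm, lsu_p, ssu_p)
        rc = {"contig_0": simkit.revcomp(asm.contigs["contig_0"])}
        res_r = rdna_hmm.cn_hmm_pipeline(rc, lsu_p, ssu_p)
        assert res_f.copy_number == res_r.copy_number == 3
        assert all(l.strand == "-" for l in res_r.loci)


class TestExtract:
    def test_extracted_its_matches_truth(self, profiles, make_genome):
        lsu_p, ssu_p = profiles
        asm, truth = make_genome(3, divergence=0.0, seed=33)
        res = rdna_hmm.cn_hmm_pipeline(asm, lsu_p, ssu_p)
        records, bed = rdna_hmm.extract_its(res, asm)
        assert len(records) == 3
        assert all(seq == truth.its_sequence for _, seq in records)
        assert all(len(seq) == 550 for _, seq in records)

    def test_minus_strand_reverse_complemented(self):
        seq = "A" * 10 + "ACGTTGCACGTTGCACGTT" + "C" * 10
        res = rdna_hmm.CNHMMResult("g", 1, [rdna_hmm.ITSLocus("c", 10, 29, "-",
                                                              "paired")])
        records, _ = rdna_hmm.extract_its(res, {"c": seq})
        assert records[0][1] == simkit.revcomp(seq[10:29])

    def test_truncated_loci_in_bed_not_fasta(self):
        loci = [rdna_hmm.ITSLocus("c", 100, 650, "+", "paired"),
                rdna_hmm.ITSLocus("c", 900, 1000, "+", "end_truncated")]
        res = rdna_hmm.CNHMMResult("g", 2, loci)
        seq = simkit.random_seq(np.random.default_rng(0), 1000)
        with pytest.warns(UserWarning, match="end-truncated"):
            records, bed = rdna_hmm.extract_its(res, {"c": seq})
        assert len(records) == 1
        assert len(bed) == 2

    def test_bed_roundtrip(self, tmp_path):
        loci = [rdna_hmm.ITSLocus("c", 100, 650, "+", "paired"),
                rdna_hmm.ITSLocus("c", 900, 1450, "-", "paired")]
        res = rdna_hmm.CNHMMResult("g", 2, loci)
        seq = simkit.random_seq(np.random.default_rng(0), 2000)
        _, bed = rdna_hmm.extract_its(res, {"c": seq})
        p = tmp_path / "loci.bed"
        p.write_text("\n".join(bed) + "\n")
        assert rdna_hmm.read_bed(p) == loci

    def test_locus_outside_contig_errors(self):
        res = rdna_hmm.CNHMMResult("g", 1,
                                   [rdna_hmm.ITSLocus("c", 100, 900, "+", "paired")])
        with pytest.raises(ValueError, match="outside"):
            rdna_hmm.extract_its(res, {"c": "ACGT" * 50})
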