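"""Amplicon alignment, pileup/variant filtering and spectrum arithmetic."""

import math

import numpy as np
import pytest

from stopkit import (
    AlignmentParams,
    VariantFilter,
    align_read,
    align_reads,
    pileup_and_filter,
    ratio_from_frequencies,
    run_spectrum_pipeline,
    spectrum,
    substitution_indel_ratio,
)
from stopkit.spectrum import orient_reference

from conftest import random_dna


def oracle_cost(read, ref, mm=2, ins=3, dele=3):
    """Cost-only full dynamic program, written independently of the package:
    read aligned end-to-end, reference ends free."""
    prev = [0] * (len(ref) + 1)
    for rb in read:
        cur = [prev[0] + ins]
        for j, qb in enumerate(ref, 1):
            cur.append(
                min(
                    prev[j - 1] + (0 if rb == qb else mm),
                    prev[j] + ins,
                    cur[j - 1] + dele,
                )
            )
        prev = cur
    return min(prev)


def mutate(rng, seq, n_sub=0, n_ins=0, n_del=0):
    s = list(seq)
    for _ in range(n_sub):
        i = rng.integers(0, len(s))
        s[i] = "ACGT"[("ACGT".index(s[i]) + 1) % 4]
    for _ in range(n_ins):
        i = rng.integers(0, len(s))
        s.insert(i, "ACGT"[rng.integers(0, 4)])
    for _ in range(n_del):
        i = rng.integers(0, len(s) - 1)
        del s[i]
    return "".join(s)


class TestAlignRead:
    def test_exact_substring_costs_nothing(self, rng):
        ref = random_dna(rng, 120)
        a = align_read(ref[30:90], ref)
        assert a.cost == 0 and a.ref_start == 30
        assert a.ops == (("M", 60),)
        assert a.identity == 1.0 and a.aligned_fraction == 1.0
        assert a.passed_filters

    def test_mismatch_cheaper_than_gap(self):
        # one substitution: mismatch costs 2, any indel detour >= 6
        ref = "AAAACCCCGGGGTTTT"
        read = "AAAACCACGGGG"
        a = align_read(read, ref)
        assert a.cost == 2
        assert all(op == "M" for op, _ in a.ops)

    def test_deletion_called_when_cheapest(self):
        ref = "ACGGTTCAATCCGGATTACG"  # aperiodic: deletion is unambiguous
        read = ref[:6] + ref[8:]  # 2-base deletion
        a = align_read(read, ref)
        assert a.cost == 6
        assert ("D", 2) in a.ops

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            align_read("ACXT", "ACGTACGT")

    @pytest.mark.parametrize("seed", range(10))
    def test_cost_equals_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_dna(rng, 120)
        for _ in range(20):
            start = int(rng.integers(0, 60))
            base = ref[start : start + 60]
            read = mutate(
                rng, base,
                n_sub=int(rng.integers(0, 4)),
                n_ins=int(rng.integers(0, 3)),
                n_del=int(rng.integers(0, 3)),
            )
            assert align_read(read, ref).cost == oracle_cost(read, ref)

    @pytest.mark.parametrize("seed", range(3))
    def test_ops_reconstruct_read_against_ref(self, seed):
        """M/I/D ops consume exactly the read and a reference span, and
        mismatch count implied by ops matches the alignment cost."""
        rng = np.random.default_rng(100 + seed)
        ref = random_dna(rng, 120)
        read = mutate(rng, ref[10:90], n_sub=2, n_ins=1, n_del=1)
        a = align_read(read, ref)
        read_used = sum(ln for op, ln in a.ops if op in "MI")
        ref_used = sum(ln for op, ln in a.ops if op in "MD")
        assert read_used == len(read)
        assert a.ref_start + ref_used <= len(ref)
        n_m = sum(ln for op, ln in a.ops if op == "M")
        n_ins = sum(ln for op, ln in a.ops if op == "I")
        n_del = sum(ln for op, ln in a.ops if op == "D")
        assert a.cost == 2 * (n_m - a.n_match) + 3 * n_ins + 3 * n_del

    def test_reverse_complement_mate_recovered(self, rng):
        from stopkit import revcomp

        ref = random_dna(rng, 120)
        (a,) = align_reads([("r/2", revcomp(ref[20:100]))], ref)
        assert a.reverse_complemented and a.cost == 0 and a.ref_start == 20


class TestPileupAndFilter:
    def test_single_low_count_variant_not_reported(self, rng):
        ref = random_dna(rng, 60)
        idx = ref.index("C")
        edited = ref[:idx] + "T" + ref[idx + 1 :]
        reads = [(f"r{i}", ref) for i in range(100)] + [("rx", edited)]
        pile = pileup_and_filter(align_reads(reads, ref), ref)
        row = pile.variants.query("pos == @idx and alt == 'T'")
        assert len(row) == 1
        assert row.iloc[0]["count"] == 1
        assert row.iloc[0]["frequency_percent"] == pytest.approx(100 / 101)
        assert not row.iloc[0]["reported"]  # count 1 < min_count 2

    def test_coverage_gate_blocks_everything(self, rng):
        ref = random_dna(rng, 60)
        idx = ref.index("C")
        edited = ref[:idx] + "T" + ref[idx + 1 :]
        reads = [(f"r{i}", edited) for i in range(9)]
        pile = pileup_and_filter(align_reads(reads, ref), ref)
        assert not pile.variants["reported"].any()  # coverage 9 < 10

    def test_empty_passing_set_warns(self, rng, caplog):
        ref = random_dna(rng, 60)
        pile = pileup_and_filter([], ref)
        assert pile.n_fragments_passing == 0
        assert pile.variants.empty

    @pytest.mark.parametrize("seed", range(5))
    def test_gates_match_independent_filter_oracle(self, seed):
        """Reported set equals applying the three gates independently."""
        rng = np.random.default_rng(seed)
        ref = random_dna(rng, 40)
        n = int(rng.integers(5, 30))
        reads = []
        for i in range(n):
            reads.append((f"r{i}", mutate(rng, ref, n_sub=int(rng.integers(0, 3)))))
        vf = VariantFilter(min_coverage=10, min_count=2, min_frequency_percent=0.5)
        pile = pileup_and_filter(align_reads(reads, ref), ref, vf)
        for row in pile.variants.itertuples():
            expect = (
                row.coverage >= vf.min_coverage
                and row.count >= vf.min_count
                and 100.0 * row.count / row.coverage >= vf.min_frequency_percent
            )
            assert row.reported == expect

    @pytest.mark.parametrize("seed", range(5))
    def test_class_counts_sum_to_coverage(self, seed):
        rng = np.random.default_rng(40 + seed)
        ref = random_dna(rng, 50)
        reads = [
            (f"r{i}", mutate(rng, ref, n_sub=1, n_del=int(rng.integers(0, 2))))
            for i in range(25)
        ]
        pile = pileup_and_filter(align_reads(reads, ref), ref)
        sums = pile.counts[["A", "C", "G", "T", "del"]].sum(axis=1)
        assert (sums == pile.counts["coverage"]).all()

    def test_loosening_thresholds_never_removes_variants(self, rng):
        ref = random_dna(rng, 50)
        reads = [(f"r{i}", mutate(rng, ref, n_sub=2)) for i in range(30)]
        alns = align_reads(reads, ref)
        strict = pileup_and_filter(alns, ref, VariantFilter(10, 2, 0.5))
        for vf in (VariantFilter(5, 2, 0.5), VariantFilter(10, 1, 0.5),
                   VariantFilter(10, 2, 0.1), VariantFilter(0, 0, 0.0)):
            loose = pileup_and_filter(alns, ref, vf)
            srep = set(map(tuple, strict.variants.query("reported")[["pos", "alt"]].values))
            lrep = set(map(tuple, loose.variants.query("reported")[["pos", "alt"]].values))
            assert srep <= lrep

    def test_paired_mates_count_fragment_once(self, rng):
        from stopkit import revcomp

        ref = random_dna(rng, 100)
        # mates fully overlap the same span; fragment must contribute 1 per position
        reads = [("f/1", ref[10:90]), ("f/2", revcomp(ref[10:90]))]
        pile = pileup_and_filter(align_reads(reads, ref), ref)
        assert pile.n_fragments_passing == 1
        assert pile.counts["coverage"].max() == 1

    def test_mate_one_wins_overlap_disagreement(self, rng):
        from stopkit import revcomp

        ref = random_dna(rng, 100)
        idx = 50
        alt = "T" if ref[idx] != "T" else "A"
        edited = ref[:idx] + alt + ref[idx + 1 :]
        reads = [("f/1", ref[10:90]), ("f/2", revcomp(edited[10:90]))]
        pile = pileup_and_filter(align_reads(reads, ref), ref)
        assert pile.counts.at[idx, ref[idx]] == 1  # mate 1's call stands
        assert pile.counts.at[idx, alt] == 0


class TestSpectrum:
    def test_all_reference_reads_give_zero_spectrum(self, rng):
        ref = random_dna(rng, 80)
        reads = [(f"r{i}", ref) for i in range(20)]
        pile = pileup_and_filter(align_reads(reads, ref), ref)
        spec = spectrum(pile, pam_start=60, window=(-22, -1))
        assert (spec.table[["A", "C", "G", "T", "del"]].values == 0).all()
        assert spec.indel_frequency_percent == 0.0
        assert spec.n_reads_passing == 20

    def test_hand_built_pileup_exact_frequencies(self, rng):
        ref = random_dna(rng, 80)
        idx = 41  # PAM-relative -19 for pam_start 60
        alt = "T" if ref[idx] != "T" else "G"
        edited = ref[:idx] + alt + ref[idx + 1 :]
        deleted = ref[:30] + ref[31:]
        reads = (
            [(f"a{i}", ref) for i in range(15)]
            + [(f"b{i}", edited) for i in range(4)]
            + [("c0", deleted)]
        )
        pile = pileup_and_filter(align_reads(reads, ref), ref)
        spec = spectrum(pile, pam_start=60, window=(-22, -1), locus_id="toy")
        assert spec.freq(-19, alt) == pytest.approx(100 * 4 / 20)
        assert spec.indel_frequency_percent == pytest.approx(100 * 1 / 20)

    def test_window_outside_amplicon_raises(self, rng):
        ref = random_dna(rng, 30)
        pile = pileup_and_filter(align_reads([("r", ref)], ref), ref)
        with pytest.raises(IndexError):
            spectrum(pile, pam_start=10, window=(-22, -1))

    def test_orient_reference_minus_strand(self):
        from stopkit import revcomp

        ref = "AAACCCGGGTTTACG"
        oref, opam = orient_reference(ref, 2, "-")
        assert oref == revcomp(ref)
        assert oref[opam : opam + 3] == revcomp(ref[2:5])


class TestSubstitutionIndelRatio:
    @pytest.mark.parametrize(
        "sub,indel,expected", [(2.19, 0.91, 2.41), (4.37, 8.48, 0.52),
                               (2.27, 0.60, 3.78), (1.0, 1.0, 1.00)]
    )
    def test_reported_ratios(self, sub, indel, expected):
        assert ratio_from_frequencies(sub, indel) == expected

    def test_zero_indel_is_infinite(self):
        assert math.isinf(ratio_from_frequencies(2.0, 0.0))

    def test_from_spectrum_object(self, rng):
        ref = random_dna(rng, 80)
        idx = 41
        base = "C"
        ref = ref[:idx] + base + ref[idx + 1 :]
        edited = ref[:idx] + "T" + ref[idx + 1 :]
        deleted = ref[:30] + ref[31:]
        reads = [(f"a{i}", ref) for i in range(16)] + [
            ("b0", edited), ("b1", edited), ("b2", edited), ("c0", deleted)
        ]
        pile = pileup_and_filter(align_reads(reads, ref), ref)
        spec = spectrum(pile, pam_start=60)
        # 3/20 C>T at -19 vs 1/20 indel reads
        assert substitution_indel_ratio(spec, [-19]) == 3.0


class TestPipelineRecovery:
    @pytest.mark.parametrize("rate", [0.005, 0.02, 0.05])
    def test_simulated_rate_recovered_within_3_se(self, rate):
        """C>T frequencies simulated at 0.5/2/5% come back within three
        binomial standard errors (50k molecules, fixed seed)."""
        from stopkit import ReadSimConfig, make_amplicon, simulate_reads

        n = 50_000
        ref = make_amplicon(250, 200, -19, seed=20)
        cfg = ReadSimConfig(
            ref=ref, pam_start=200,
            per_position_sub_rates={(-19, "T"): rate},
            indel_rate=0.0, seq_error_rate=0.0,
            n_reads=n, seed=7,
        )
        reads, truth = simulate_reads(cfg)
        spec = run_spectrum_pipeline(reads, ref, 200)
        se = math.sqrt(rate * (1 - rate) / n)
        assert spec.freq(-19, "T") == pytest.approx(100 * rate, abs=300 * se)
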