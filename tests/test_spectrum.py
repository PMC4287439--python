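import itertools

import numpy as np
import pytest

from meiomut.spectrum import (
    MutationRecord,
    SpectrumSummary,
    classify_isolate,
    classify_mutation,
    compare_spectra,
    positional_distribution,
    summarize_spectrum,
    window_index,
)

PURINES = {"A", "G"}


def rec(ref, alt, position=10, isolate="i0", phase="mitosis"):
    return MutationRecord(isolate, position, ref, alt, phase)


class TestClassifyMutation:
    def test_transition(self):
        assert classify_mutation(rec("G", "A")) == ("substitution", "transition")

    def test_transversion(self):
        assert classify_mutation(rec("G", "T")) == ("substitution", "transversion")

    def test_all_twelve_substitutions_against_oracle(self):
        # brute force: transition iff both bases are purines or both pyrimidines
        for ref, alt in itertools.permutations("ACGT", 2):
            major, minor = classify_mutation(rec(ref, alt))
            assert major == "substitution"
            same_family = ({ref, alt} <= PURINES) or ({ref, alt} <= {"C", "T"})
            assert minor == ("transition" if same_family else "transversion")

    def test_frameshift_contraction(self):
        assert classify_mutation(rec("AA", "A")) == ("frameshift", "contraction")

    def test_frameshift_expansion(self):
        assert classify_mutation(rec("A", "AA")) == ("frameshift", "expansion")

    def test_insertion_with_empty_ref(self):
        assert classify_mutation(rec("", "T")) == ("frameshift", "expansion")

    def test_in_frame_indel_separate_class(self):
        assert classify_mutation(rec("AAAG", "A")) == ("in_frame_indel", None)

    def test_equal_length_multibase_is_complex(self):
        assert classify_mutation(rec("AC", "GT")) == ("complex", None)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            rec("A", "A")

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            rec("N", "A")


class TestClassifyIsolate:
    def test_single_record_passthrough(self):
        assert classify_isolate([rec("G", "A")]) == ("substitution", "transition")

    def test_two_records_complex(self):
        records = [rec("G", "A"), rec("C", "T", position=500)]
        assert classify_isolate(records) == ("complex", None)

    def test_empty_isolate_rejected(self):
        with pytest.raises(ValueError):
            classify_isolate([])


class TestSummarize:
    def _records(self):
        out = []
        # meiosis: 20 frameshifts, 72 substitutions, 4 complex = 96 isolates
        for i in range(15):
            out.append(rec("AA", "A", isolate=f"me_fs{i}", phase="meiosis"))
        for i in range(5):
            out.append(rec("A", "AA", isolate=f"me_fe{i}", phase="meiosis"))
        for i in range(44):
            out.append(rec("G", "A", isolate=f"me_ts{i}", phase="meiosis"))
        for i in range(28):
            out.append(rec("G", "T", isolate=f"me_tv{i}", phase="meiosis"))
        for i in range(4):
            out.append(rec("G", "A", isolate=f"me_cx{i}", phase="meiosis"))
            out.append(rec("C", "A", isolate=f"me_cx{i}", phase="meiosis", position=900))
        # mitosis: 8 frameshifts of 80
        for i in range(6):
            out.append(rec("CC", "C", isolate=f"mi_fs{i}", phase="mitosis"))
        for i in range(2):
            out.append(rec("C", "CC", isolate=f"mi_fe{i}", phase="mitosis"))
        for i in range(41):
            out.append(rec("A", "G", isolate=f"mi_ts{i}", phase="mitosis"))
        for i in range(31):
            out.append(rec("A", "C", isolate=f"mi_tv{i}", phase="mitosis"))
        return out

    def test_published_percentages(self):
        summaries = summarize_spectrum(self._records())
        me, mi = summaries["meiosis"], summaries["mitosis"]
        assert (me.n_total, me.n_frameshift, me.n_complex) == (96, 20, 4)
        assert me.percent("frameshift") == 21
        assert (mi.n_total, mi.n_frameshift) == (80, 8)
        assert mi.percent("frameshift") == 10

    def test_splits_sum_to_class_totals(self):
        for s in summarize_spectrum(self._records()).values():
            assert s.n_contraction + s.n_expansion == s.n_frameshift
            assert s.n_transition + s.n_transversion == s.n_substitution
            assert (
                s.n_frameshift + s.n_substitution + s.n_complex + s.n_in_frame_indel
                == s.n_total
            )

    def test_single_class_is_100_percent(self):
        records = [rec("G", "A", isolate=f"i{k}") for k in range(5)]
        s = summarize_spectrum(records)["mitosis"]
        assert s.percent("substitution") == 100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_spectrum([])

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            SpectrumSummary(
                n_total=10, n_frameshift=2, n_contraction=1, n_expansion=0,
                n_substitution=8, n_transition=4, n_transversion=4, n_complex=0,
            )


class TestCompareSpectra:
    def _summary(self, fs, sub, cx=0):
        return SpectrumSummary(
            n_total=fs + sub + cx, n_frameshift=fs, n_contraction=fs, n_expansion=0,
            n_substitution=sub, n_transition=sub, n_transversion=0, n_complex=cx,
        )

    def test_identical_spectra(self):
        a = self._summary(10, 90)
        _, p = compare_spectra(a, a)
        assert p > 0.99

    def test_published_frameshift_table(self):
        # hand chi-square on [[8,72],[20,76]]: 176*(8*76-72*20)^2/(80*96*28*148)
        a = self._summary(8, 72)
        b = self._summary(20, 76)
        stat, p = compare_spectra(a, b)
        assert stat == pytest.approx(3.828, abs=0.01)
        # an uncorrected 2x2 gives p ~ 0.05, not the source's quoted 0.02
        assert 0.04 < p < 0.06

    def test_extreme_difference(self):
        a = self._summary(100, 0)
        b = self._summary(0, 100)
        _, p = compare_spectra(a, b)
        assert p < 1e-10

    def test_full_mode_runs(self):
        a = self._summary(8, 72, cx=0)
        b = self._summary(20, 72, cx=4)
        stat, p = compare_spectra(a, b, mode="full")
        assert 0 <= p <= 1

    def test_unknown_mode_rejected(self):
        a = self._summary(5, 5)
        with pytest.raises(ValueError):
            compare_spectra(a, a, mode="bogus")


class TestPositionalDistribution:
    def test_window_boundaries(self):
        assert window_index(1) == 0
        assert window_index(200) == 0
        assert window_index(201) == 1

    def test_counts_sum_and_order_invariance(self, rng):
        positions = rng.integers(1, 1774, size=60)
        records = [rec("G", "A", position=int(p), isolate=f"i{k}") for k, p in enumerate(positions)]
        other = [rec("G", "T", position=int(p), isolate=f"j{k}", phase="meiosis")
                 for k, p in enumerate(positions)]
        counts, _ = positional_distribution(
            {"a": records, "b": other}, orf_length=1773
        )
        assert counts["a"].sum() == 60
        shuffled, _ = positional_distribution(
            {"a": list(reversed(records)), "b": other}, orf_length=1773
        )
        np.testing.assert_array_equal(counts["a"], shuffled["a"])

    def test_out_of_orf_excluded(self, caplog):
        records = [rec("G", "A", position=1, isolate="ok"),
                   rec("G", "A", position=450, isolate="ok2"),
                   rec("G", "A", position=2000, isolate="far")]
        other = [rec("G", "T", position=5, isolate="x", phase="meiosis"),
                 rec("G", "T", position=300, isolate="y", phase="meiosis")]
        with caplog.at_level("WARNING", logger="meiomut.spectrum"):
            counts, _ = positional_distribution({"a": records, "b": other}, orf_length=1773)
        assert counts["a"].sum() == 2
        assert "beyond ORF" in caplog.text

    def test_concentrated_vs_uniform_significant(self, rng):
        concentrated = [rec("G", "A", position=int(p), isolate=f"i{k}")
                        for k, p in enumerate(rng.integers(1, 201, size=80))]
        uniform = [rec("G", "T", position=int(p), isolate=f"j{k}", phase="meiosis")
                   for k, p in enumerate(rng.integers(1, 1774, size=80))]
        _, p = positional_distribution({"a": concentrated, "b": uniform}, orf_length=1773)
        assert p < 0.001

    def test_null_simulation_mostly_nonsignificant(self, rng):
        hits = 0
        for _ in range(100):
            a = [rec("G", "A", position=int(p), isolate=f"i{k}")
                 for k, p in enumerate(rng.integers(1, 1774, size=80))]
            b = [rec("G", "T", position=int(p), isolate=f"j{k}", phase="meiosis")
                 for k, p in enumerate(rng.integers(1, 1774, size=96))]
            _, p = positional_distribution({"a": a, "b": b}, orf_length=1773)
            if p > 0.05:
                hits += 1
        assert hits >= 90

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            positional_distribution({"a": [rec("G", "A")]}, orf_length=1773)
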