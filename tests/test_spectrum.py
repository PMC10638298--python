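"""Substitution classification, frequencies, means, background subtraction."""

import numpy as np
import pytest

from dhmut.caller import MutationRecord
from dhmut.spectrum import (
    SpectrumReport,
    SubstitutionClass,
    classify_substitution,
    compare_spectra,
    compute_frequency,
    mean_frequency,
    per_mb,
    spectrum_summary,
    subtract_background,
)


def rec(ref, mut, pos=1, sample="s1", in_gene=False):
    return MutationRecord(
        sample_id=sample,
        chromosome="chr1",
        position=pos,
        parental_base=ref,
        mutant_base=mut,
        substitution_class=classify_substitution(ref, mut),
        in_gene_region=in_gene,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "ref,mut,expected",
        [
            ("G", "A", SubstitutionClass.GC_to_AT),
            ("C", "T", SubstitutionClass.GC_to_AT),
            ("A", "G", SubstitutionClass.AT_to_GC),
            ("T", "C", SubstitutionClass.AT_to_GC),
            ("A", "C", SubstitutionClass.AT_to_CG),
            ("T", "G", SubstitutionClass.AT_to_CG),
            ("A", "T", SubstitutionClass.AT_to_TA),
            ("T", "A", SubstitutionClass.AT_to_TA),
            ("G", "T", SubstitutionClass.GC_to_TA),
            ("C", "A", SubstitutionClass.GC_to_TA),
            ("G", "C", SubstitutionClass.GC_to_CG),
            ("C", "G", SubstitutionClass.GC_to_CG),
        ],
    )
    def test_strand_symmetric_mapping(self, ref, mut, expected):
        assert classify_substitution(ref, mut) is expected

    def test_partition_is_exhaustive_two_per_class(self):
        """All 12 ordered substitutions land in 6 classes, 2 each."""
        from collections import Counter

        counts = Counter(
            classify_substitution(r, m) for r in "ACGT" for m in "ACGT" if r != m
        )
        assert set(counts) == set(SubstitutionClass)
        assert all(v == 2 for v in counts.values())

    @pytest.mark.parametrize("ref,mut", [("A", "A"), ("N", "A"), ("G", "X"), ("", "A")])
    def test_invalid_bases_rejected(self, ref, mut):
        with pytest.raises(ValueError):
            classify_substitution(ref, mut)


class TestFrequency:
    def test_zero_mutations_gives_zero_ratio(self):
        rep = compute_frequency([], callable_size=10**6, sample_id="s")
        assert rep.ratio_genome == 0.0
        assert rep.ratio_genome_display == 0.0

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            per_mb(5, 0)

    def test_gene_counts_use_flagged_records_only(self):
        muts = [rec("G", "A", pos=i, in_gene=(i % 3 == 0)) for i in range(1, 10)]

        class Genes:
            size = 500_000

        rep = compute_frequency(muts, callable_size=2_000_000, gene_intervals=Genes())
        assert rep.n_mutations_genome == 9
        assert rep.n_mutations_gene == 3
        assert rep.ratio_genome == pytest.approx(4.5)
        assert rep.ratio_gene == pytest.approx(6.0)
        assert rep.n_mutations_gene <= rep.n_mutations_genome

    def test_pooled_ratio_is_weighted_combination(self, rng):
        """Additivity: pooling subsets over one denominator adds their ratios."""
        size = 3_456_789
        n_a, n_b = 123, 456
        assert per_mb(n_a + n_b, size) == pytest.approx(per_mb(n_a, size) + per_mb(n_b, size))


class TestMeanAndSubtraction:
    def test_mean_of_single_report_is_itself(self):
        assert mean_frequency([1.73]) == pytest.approx(1.73)

    def test_empty_mean_rejected(self):
        with pytest.raises(ValueError):
            mean_frequency([])

    def test_mean_accepts_reports(self):
        reps = [compute_frequency([], 10**6, sample_id=s) for s in "ab"]
        assert mean_frequency(reps) == 0.0

    def test_equal_means_subtract_to_zero(self):
        assert subtract_background(1.0, 1.0) == 0.0

    def test_negative_difference_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert subtract_background(1.0, 1.2) == 0.0


class TestSpectrumSummary:
    def test_hand_count(self):
        reps = spectrum_summary([rec("G", "A", 1), rec("C", "T", 2), rec("A", "G", 3)])
        assert reps.counts[SubstitutionClass.GC_to_AT] == 2
        assert reps.counts[SubstitutionClass.AT_to_GC] == 1
        assert reps.total == 3
        assert reps.gc_to_at_fraction == pytest.approx(2 / 3)

    def test_empty_input_all_zero_fraction_missing(self):
        reps = spectrum_summary([])
        assert reps.total == 0
        assert all(v == 0 for v in reps.counts.values())
        assert reps.gc_to_at_fraction is None

    def test_counts_sum_to_total(self, rng):
        bases = "ACGT"
        muts = []
        for i in range(200):
            r = bases[rng.integers(4)]
            m = rng.choice([b for b in bases if b != r])
            muts.append(rec(r, str(m), pos=i + 1))
        reps = spectrum_summary(muts)
        assert sum(reps.counts.values()) == reps.total == 200


def _report(sample, counts):
    full = {cls: 0 for cls in SubstitutionClass}
    full.update(counts)
    total = sum(full.values())
    frac = full[SubstitutionClass.GC_to_AT] / total if total else None
    return SpectrumReport(sample_id=sample, counts=full, total=total, gc_to_at_fraction=frac)


class TestCompareSpectra:
    def test_identical_groups_zero_effect_nonsignificant(self):
        counts = {SubstitutionClass.GC_to_AT: 10, SubstitutionClass.AT_to_GC: 10}
        a = [_report(f"a{i}", counts) for i in range(3)]
        b = [_report(f"b{i}", counts) for i in range(3)]
        table = compare_spectra(a, b, seed=1)
        assert (table["effect"] == 0).all()
        assert (table["p_value"] > 0.5).all()

    def test_single_sample_groups_untestable(self):
        a = [_report("a", {SubstitutionClass.GC_to_AT: 5})]
        b = [_report("b", {SubstitutionClass.AT_to_TA: 5})]
        table = compare_spectra(a, b, seed=1)
        assert not table["testable"].any()
        assert table["p_value"].isna().all()
        assert table.loc[SubstitutionClass.GC_to_AT.label, "effect"] == pytest.approx(-1.0)

    def test_ems_shift_detected_with_positive_effect(self, rng):
        """An EMS-like group shows a positive G/C->A/T fraction effect."""
        ctrl = [
            _report(f"c{i}", {SubstitutionClass.GC_to_AT: int(rng.poisson(30)),
                              SubstitutionClass.AT_to_GC: int(rng.poisson(25)),
                              SubstitutionClass.GC_to_TA: int(rng.poisson(20))})
            for i in range(3)
        ]
        trt = [
            _report(f"t{i}", {SubstitutionClass.GC_to_AT: int(rng.poisson(60)),
                              SubstitutionClass.AT_to_GC: int(rng.poisson(25)),
                              SubstitutionClass.GC_to_TA: int(rng.poisson(20))})
            for i in range(3)
        ]
        table = compare_spectra(ctrl, trt, seed=2)
        assert table.loc[SubstitutionClass.GC_to_AT.label, "effect"] > 0
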