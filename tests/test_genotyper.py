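"""Amplicon genotyping: filtering, variant classification, zygosity, cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from calluscope.genotyper import (
    LineCall,
    LocusCall,
    NoCallError,
    TargetSpec,
    VariantRecord,
    call_line,
    call_locus,
    classify_variant,
    classify_zygosity,
    filter_low_frequency,
    genotype_cohort,
    locus_mutation_frequency,
    round_half_away,
    summarize_cohort,
)

from conftest import COHORT_COUNTS, COHORT_RATES


def _variants(counts, line="L1", locus="A"):
    return [VariantRecord(line, locus, f"seq{i}", c) for i, c in enumerate(counts)]


class TestFilter:
    def test_exactly_one_percent_kept(self):
        kept = filter_low_frequency(_variants([990, 10]))
        assert len(kept) == 2

    def test_below_one_percent_removed_and_renormalized(self):
        kept = filter_low_frequency(_variants([995, 5]))
        assert len(kept) == 1
        assert kept[0].frequency == pytest.approx(1.0)

    def test_prefilter_denominator_option(self):
        kept = filter_low_frequency(_variants([995, 5]), renormalize=False)
        assert kept[0].frequency == pytest.approx(0.995)

    def test_all_filtered_is_no_call(self):
        with pytest.raises(NoCallError):
            filter_low_frequency(_variants([0, 0]))

    def test_matches_threshold_oracle(self, rng):
        counts = rng.integers(0, 2000, size=8).tolist()
        counts[0] += 1  # ensure nonzero total
        total = sum(counts)
        kept = filter_low_frequency(_variants(counts))
        expected = {i for i, c in enumerate(counts) if c / total >= 0.01}
        assert {int(v.variant_seq[3:]) for v in kept} == expected

    def test_idempotent(self, rng):
        counts = rng.integers(0, 5000, size=6).tolist()
        counts[0] += 1
        once = filter_low_frequency(_variants(counts))
        twice = filter_low_frequency(
            [VariantRecord(v.line_id, v.locus_id, v.variant_seq, v.read_count) for v in once]
        )
        assert [(v.variant_seq, v.read_count) for v in once] == [
            (v.variant_seq, v.read_count) for v in twice
        ]
        assert [v.frequency for v in once] == pytest.approx([v.frequency for v in twice])


class TestClassifyVariant:
    def test_wildtype(self, demo_targets):
        t = demo_targets[0]
        cls, subs, delta = classify_variant(t, t.reference_amplicon)
        assert (cls, subs, delta) == ("wildtype", [], 0)

    def test_substitution_in_protospacer(self, demo_targets):
        t = demo_targets[0]
        # protospacer position 5 is a C by construction; edit it to T
        amp_pos = t.protospacer_start + 4
        ref = t.reference_amplicon
        variant = ref[: amp_pos - 1] + "T" + ref[amp_pos:]
        cls, subs, delta = classify_variant(t, variant)
        assert cls == "substitution" and delta == 0
        assert subs == [(5, "C", "T", True)]

    def test_substitution_outside_protospacer(self, demo_targets):
        t = demo_targets[0]
        ref = t.reference_amplicon
        pos = 10  # inside the left flank
        alt = "A" if ref[pos - 1] != "A" else "G"
        variant = ref[: pos - 1] + alt + ref[pos:]
        cls, subs, _ = classify_variant(t, variant)
        assert cls == "substitution"
        assert subs == [(pos, ref[pos - 1], alt, False)]

    def test_deletion_in_protospacer(self, demo_targets):
        t = demo_targets[0]
        i = t.protospacer_start + 9
        ref = t.reference_amplicon
        variant = ref[: i - 1] + ref[i:]
        cls, subs, delta = classify_variant(t, variant)
        assert cls == "indel" and delta == -1

    def test_insertion(self, demo_targets):
        t = demo_targets[0]
        i = t.protospacer_start + 9
        ref = t.reference_amplicon
        variant = ref[:i] + "A" + ref[i:]
        cls, _, delta = classify_variant(t, variant)
        assert cls == "indel" and delta == 1

    def test_complex(self, demo_targets):
        t = demo_targets[0]
        ref = t.reference_amplicon
        i = t.protospacer_start + 9
        variant = ref[: i - 1] + ref[i:]  # deletion
        alt = "A" if variant[4] != "A" else "G"
        variant = variant[:4] + alt + variant[5:]  # plus a distant mismatch
        cls, subs, delta = classify_variant(t, variant)
        assert cls == "complex" and delta == -1 and len(subs) >= 1

    def test_non_dna_errors(self, demo_targets):
        with pytest.raises(ValueError):
            classify_variant(demo_targets[0], "ACGU")
        with pytest.raises(ValueError):
            classify_variant(demo_targets[0], "")

    def test_minus_strand_coordinates(self):
        # spacer on the '-' strand: protospacer coordinates count from the
        # PAM-distal end along the reverse complement
        spacer = "ACGTACGTACCGTACGTACG"
        left, right = "GGGTTT", "AAACCCGGG"
        amplicon = left + "CCT" + _revcomp(spacer) + right  # PAM CCT = revcomp(AGG)
        start = len(left) + 3 + 20  # amplicon position of spacer base 1
        t = TargetSpec("X", amplicon, spacer, start, spacer_strand="-")
        # edit spacer position 5 (A in ACGTA...): forward base is complement T
        amp_pos = start - 4
        assert amplicon[amp_pos - 1] == "T"
        variant = amplicon[: amp_pos - 1] + "C" + amplicon[amp_pos:]
        cls, subs, _ = classify_variant(t, variant)
        assert cls == "substitution"
        assert subs == [(5, "A", "G", True)]


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestLocusFrequency:
    def _classified(self, spec):
        out = []
        for i, (cls, freq) in enumerate(spec):
            v = VariantRecord("L", "A", f"s{i}", 0, frequency=freq, mutation_class=cls)
            out.append(v)
        return out

    def test_sums(self):
        vs = self._classified(
            [("wildtype", 0.6), ("substitution", 0.3), ("indel", 0.1)]
        )
        assert locus_mutation_frequency(vs) == pytest.approx((0.4, 0.1))

    def test_all_wildtype(self):
        vs = self._classified([("wildtype", 1.0)])
        assert locus_mutation_frequency(vs) == (0.0, 0.0)

    def test_matches_summation_oracle(self, rng):
        classes = ["wildtype", "substitution", "indel", "complex"]
        freqs = rng.dirichlet(np.ones(6))
        picks = [classes[i] for i in rng.integers(0, 4, size=6)]
        vs = self._classified(list(zip(picks, freqs)))
        mut, indel = locus_mutation_frequency(vs)
        assert mut == pytest.approx(
            sum(f for c, f in zip(picks, freqs) if c != "wildtype")
        )
        assert indel == pytest.approx(
            sum(f for c, f in zip(picks, freqs) if c in ("indel", "complex"))
        )

    def test_frequencies_must_sum_to_one(self):
        vs = self._classified([("wildtype", 0.4)])
        with pytest.raises(ValueError):
            locus_mutation_frequency(vs)


class TestZygosity:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (0.95, "homozygous"),
            (0.901, "homozygous"),
            (0.90, "heterozygous"),
            (0.20, "heterozygous"),
            (0.199, "chimeric"),
            (0.0, "wildtype"),
            (1.0, "homozygous"),
        ],
    )
    def test_boundaries(self, f, expected):
        assert classify_zygosity(f) == expected

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            classify_zygosity(1.01)
        with pytest.raises(ValueError):
            classify_zygosity(-0.1)

    def test_partition_of_unit_interval(self):
        """Every frequency in a fine grid gets exactly one class."""
        grid = np.linspace(0.0, 1.0, 10_001)
        classes = [classify_zygosity(float(f)) for f in grid]
        assert set(classes) == {"wildtype", "chimeric", "heterozygous", "homozygous"}
        # classes are ordered along the grid: wt | chimeric | het | homo
        order = {"wildtype": 0, "chimeric": 1, "heterozygous": 2, "homozygous": 3}
        ranks = [order[c] for c in classes]
        assert ranks == sorted(ranks)


def _locus(zyg, freq, indel_freq=0.0, line="L1", locus="A"):
    return LocusCall(line, locus, freq, zyg, indel_freq > 0, indel_freq)


class TestCallLine:
    def test_homozygous_at_one_locus(self):
        call = call_line([_locus("homozygous", 0.95), _locus("wildtype", 0.0, locus="B")])
        assert call.edited and call.homozygous

    def test_chimeric_only_not_edited(self):
        call = call_line([_locus("chimeric", 0.1), _locus("chimeric", 0.15, locus="B")])
        assert not call.edited and not call.homozygous

    def test_indel_threshold_rule(self):
        call = call_line([_locus("heterozygous", 0.5, indel_freq=0.25)])
        assert call.indel_line
        call = call_line([_locus("heterozygous", 0.5, indel_freq=0.1)])
        assert not call.indel_line
        call = call_line(
            [_locus("heterozygous", 0.5, indel_freq=0.1)], indel_rule="any"
        )
        assert call.indel_line

    def test_matches_rule_oracle(self, rng):
        for _ in range(50):
            f1, f2 = rng.uniform(0, 1, size=2)
            i1, i2 = rng.uniform(0, 1) * f1, rng.uniform(0, 1) * f2
            calls = [
                _locus(classify_zygosity(f1), f1, indel_freq=i1),
                _locus(classify_zygosity(f2), f2, indel_freq=i2, locus="B"),
            ]
            got = call_line(calls)
            assert got.edited == (f1 >= 0.20 or f2 >= 0.20)
            assert got.homozygous == (f1 > 0.90 or f2 > 0.90)
            assert got.indel_line == (i1 >= 0.20 or i2 >= 0.20)
            assert not got.homozygous or got.edited


class TestSummarizeCohort:
    def _lines(self, n, n_edited, n_homo, n_indel):
        out = []
        for i in range(n):
            out.append(
                LineCall(
                    f"L{i}", [], edited=i < n_edited, homozygous=i < n_homo,
                    indel_line=i < n_indel,
                )
            )
        return out

    @pytest.mark.parametrize("construct", sorted(COHORT_COUNTS))
    def test_published_cohort_arithmetic(self, construct):
        """Count columns reproduce the printed per-construct rates."""
        n, e, h, i = COHORT_COUNTS[construct]
        s = summarize_cohort(self._lines(n, e, h, i), construct)
        assert (s.editing_efficiency, s.homozygous_rate, s.indel_rate) == COHORT_RATES[
            construct
        ]
        assert s.n_homozygous <= s.n_edited <= s.n_genotyped

    def test_zero_edited(self):
        s = summarize_cohort(self._lines(10, 0, 0, 0))
        assert (s.editing_efficiency, s.homozygous_rate, s.indel_rate) == (0.0, 0.0, 0.0)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(14.25, 1) == 14.3
        assert round_half_away(0.05, 1) == 0.1
        assert round_half_away(-0.05, 1) == -0.1


class TestGenotypeCohort:
    def test_end_to_end_simple(self, demo_targets):
        t = demo_targets[0]
        ref = t.reference_amplicon
        amp_pos = t.protospacer_start + 4
        edited = ref[: amp_pos - 1] + "T" + ref[amp_pos:]
        table = pd.DataFrame(
            [
                ("L1", t.locus_id, ref, 50),
                ("L1", t.locus_id, edited, 4950),
                ("L2", t.locus_id, ref, 5000),
            ],
            columns=["line_id", "locus_id", "variant_seq", "read_count"],
        )
        _, locus_frame, line_frame, summary = genotype_cohort(
            table, {t.locus_id: t}, construct_id="demo"
        )
        assert locus_frame.set_index("line_id").loc["L1", "zygosity"] == "homozygous"
        assert locus_frame.set_index("line_id").loc["L2", "zygosity"] == "wildtype"
        assert summary.n_genotyped == 2 and summary.n_edited == 1
        assert summary.editing_efficiency == 50.0

    def test_unknown_locus_errors(self, demo_targets):
        table = pd.DataFrame(
            [("L1", "nope", "ACGT", 10)],
            columns=["line_id", "locus_id", "variant_seq", "read_count"],
        )
        with pytest.raises(ValueError, match="nope"):
            genotype_cohort(table, {t.locus_id: t for t in demo_targets})
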