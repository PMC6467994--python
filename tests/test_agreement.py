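"""Amalgamation, Jaccard comparisons, the 10% area rule, cohort statistics."""

import math

import numpy as np
import pytest

from concord.agreement import (
    AgreementResult,
    area_weighted_mean_ji,
    classify_area_relation,
    cohort_summary,
    cross_modality_jaccard,
    interobserver_jaccard,
    merge_confluent,
    paired_t_test,
    read_agreements,
    round_half_up,
    two_by_two_chisq,
    write_agreements,
)
from concord.cohorts import agreements_from_counts, cohort_from_counts
from concord.errors import (
    DegenerateTableError,
    EmptyAnnotationError,
    InconsistentGroupError,
    InsufficientDataError,
    UndefinedReferenceAreaError,
)
from concord.geometry import Polygon2D
from concord.io_annotations import Annotation
from concord.registration import SimilarityTransform

from conftest import union_find_components


def square(x0, y0, side=10.0):
    return Polygon2D(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    )


def annot(poly, eye="e1", modality="OCTA", grader="g1", label="A", px=0.01):
    return Annotation(eye, modality, grader, label, poly, px)


class TestMergeConfluent:
    def test_far_apart_stay_separate(self):
        # 5 mm apart at 0.01 mm/px = 500 px gap
        regions = merge_confluent(
            [annot(square(0, 0)), annot(square(510, 0))], gap_tolerance=0.0
        )
        assert len(regions) == 2

    def test_overlapping_merge(self):
        regions = merge_confluent(
            [annot(square(0, 0)), annot(square(5, 5))], gap_tolerance=0.0
        )
        assert len(regions) == 1
        assert regions[0].area_mm2() <= (100 + 100) * 0.01**2
        assert regions[0].area_mm2() == pytest.approx(175 * 0.01**2)

    def test_chain_merges_transitively(self):
        # three squares: 1 touches 2, 2 touches 3, but 1 and 3 are apart
        chain = [annot(square(0, 0)), annot(square(9, 0)), annot(square(18, 0))]
        regions = merge_confluent(chain, gap_tolerance=0.0)
        assert len(regions) == 1

    def test_matches_union_find_oracle(self, rng):
        """Component structure equals union-find on the proximity graph."""
        px = 0.01
        for _ in range(10):
            polys = [
                square(float(x), float(y), side=8.0)
                for x, y in rng.uniform(0, 60, size=(8, 2))
            ]
            annots = [annot(p) for p in polys]
            gap_mm = 0.02
            shapes = [p.to_shapely() for p in polys]
            edges = [
                (i, j)
                for i in range(8)
                for j in range(i + 1, 8)
                if shapes[i].distance(shapes[j]) * px <= gap_mm
            ]
            expected = union_find_components(8, edges)
            regions = merge_confluent(annots, gap_tolerance=gap_mm)
            assert len(regions) == len(expected)
            assert sorted(len(r.polygons) for r in regions) == sorted(
                len(c) for c in expected
            )

    def test_mixed_labels_rejected(self):
        with pytest.raises(InconsistentGroupError):
            merge_confluent([annot(square(0, 0)), annot(square(1, 1), label="C")])

    def test_empty_input(self):
        assert merge_confluent([]) == []


class TestInterobserver:
    def test_identical_annotations_ji_one(self):
        r1 = merge_confluent([annot(square(0, 0))])
        r2 = merge_confluent([annot(square(0, 0), grader="g2")])
        res = interobserver_jaccard(r1[0], r2[0])
        assert res.jaccard == 1.0
        assert res.comparison == "interobserver_octa"

    def test_disjoint_circumcircles_ji_zero(self):
        r1 = merge_confluent([annot(square(0, 0))])
        r2 = merge_confluent([annot(square(1000, 1000), grader="g2")])
        assert interobserver_jaccard(r1[0], r2[0]).jaccard == 0.0

    def test_symmetric_in_graders(self, rng):
        r1 = merge_confluent([annot(square(0, 0, 20))])
        r2 = merge_confluent([annot(square(8, 4, 18), grader="g2")])
        a = interobserver_jaccard(r1[0], r2[0])
        b = interobserver_jaccard(r2[0], r1[0])
        assert a.jaccard == pytest.approx(b.jaccard)

    def test_mismatched_modalities_rejected(self):
        r1 = merge_confluent([annot(square(0, 0))])
        r2 = merge_confluent(
            [annot(square(0, 0), modality="ICGA_mid", label="hyper")]
        )
        with pytest.raises(InconsistentGroupError):
            interobserver_jaccard(r1[0], r2[0])


class TestCrossModality:
    def test_identity_transform_identical_region(self):
        octa = merge_confluent([annot(square(100, 100))])[0]
        icga = merge_confluent(
            [annot(square(100, 100), modality="ICGA_mid", label="hyper")]
        )[0]
        res = cross_modality_jaccard(octa, icga, SimilarityTransform.identity())
        assert res.jaccard == 1.0
        assert res.comparison == "octa_vs_icga"
        assert res.relation == "equal"

    def test_out_of_field_warning(self):
        octa = merge_confluent([annot(square(100, 100))])[0]
        icga = merge_confluent(
            [annot(square(100, 100), modality="ICGA_mid", label="hyper")]
        )[0]
        t = SimilarityTransform(1.0, 0.0, (5000.0, 5000.0))
        with pytest.warns(UserWarning, match="outside"):
            res = cross_modality_jaccard(octa, icga, t, field_of_view_mm=6.0)
        assert res.jaccard == 0.0  # still computed

    def test_areas_reported_in_mm2(self):
        octa = merge_confluent([annot(square(0, 0, side=100))])[0]
        icga = merge_confluent(
            [annot(square(0, 0, side=100), modality="ICGA_mid", label="hyper")]
        )[0]
        res = cross_modality_jaccard(octa, icga, SimilarityTransform.identity())
        assert res.area_first == pytest.approx(1.0)  # 100 px * 0.01 mm

    def test_empty_region_rejected(self):
        octa = merge_confluent([annot(square(0, 0))])[0]
        empty = AgreementResult  # placeholder, not a region
        with pytest.raises(EmptyAnnotationError):
            cross_modality_jaccard(
                octa,
                octa.__class__(
                    eye_id="e1", modality="ICGA_mid", grader="g1",
                    label="hyper", polygons=(), pixel_size=0.01,
                ),
                SimilarityTransform.identity(),
            )


class TestAreaRelation:
    @pytest.mark.parametrize(
        "octa, icga, expected",
        [
            (10.5, 10.0, "equal"),  # diff 0.5 <= 1.0
            (11.0, 10.0, "equal"),  # boundary counts as equal
            (12.0, 10.0, "larger"),
            (8.5, 10.0, "smaller"),
        ],
    )
    def test_ten_percent_rule(self, octa, icga, expected):
        assert classify_area_relation(octa, icga) == expected

    def test_zero_tolerance_is_strict_trichotomy(self):
        assert classify_area_relation(10.0, 10.0, tolerance=0.0) == "equal"
        assert classify_area_relation(10.0001, 10.0, tolerance=0.0) == "larger"
        assert classify_area_relation(9.9999, 10.0, tolerance=0.0) == "smaller"

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedReferenceAreaError):
            classify_area_relation(1.0, 0.0)


class TestPairedT:
    def test_identical_samples(self):
        assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_hand_computed_example(self):
        """Differences (-1,-1,-2,-2): t = mean(d)/(sd(d)/sqrt(n)) = -5.196..."""
        t, p = paired_t_test([1, 2, 3, 4], [2, 3, 5, 6])
        d = np.array([-1, -1, -2, -2], float)
        expect = d.mean() / (d.std(ddof=1) / 2)
        assert t == pytest.approx(expect)
        assert t == pytest.approx(-3 * math.sqrt(3), rel=1e-12)

    def test_matches_closed_form_on_random_inputs(self, rng):
        """Statistic and p agree with the textbook closed form to 6 figures."""
        from scipy import stats

        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            t, p = paired_t_test(x, y)
            d = x - y
            t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            p_ref = 2 * stats.t.sf(abs(t_ref), n - 1)
            assert t == pytest.approx(t_ref, rel=1e-6)
            assert p == pytest.approx(p_ref, rel=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            paired_t_test([1.0], [2.0])


class TestChiSquared:
    def test_balanced_table(self):
        chi2, p = two_by_two_chisq(10, 10, 10, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_closed_form(self):
        """chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), no correction."""
        a, b, c, d = 36, 6, 13, 11
        chi2, p = two_by_two_chisq(a, b, c, d, yates=False)
        n = a + b + c + d
        expect = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert chi2 == pytest.approx(expect, rel=1e-12)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(expect, 1), rel=1e-9)

    def test_yates_reduces_statistic(self):
        plain, _ = two_by_two_chisq(36, 6, 13, 11, yates=False)
        corrected, _ = two_by_two_chisq(36, 6, 13, 11, yates=True)
        assert corrected < plain

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            two_by_two_chisq(0, 0, 5, 5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            two_by_two_chisq(-1, 2, 3, 4)


class TestCohortSummary:
    def test_prevalence_percents_from_count_fixture(self):
        """A 66-eye cohort with 61/54/66 type A/B/C reproduces the printed
        percentages after half-up 1-decimal rounding."""
        records = cohort_from_counts(
            n_all_three=54, n_a_c_only=7, n_c_only=5, n_acute=42,
            n_type_b_acute=36,
        )
        s = cohort_summary(records)
        assert s.n_eyes == 66
        assert s.percents["type_a"] == 92.4
        assert s.percents["type_b"] == 81.8
        assert s.percents["type_c"] == 100.0
        assert s.percents["all_three"] == 81.8
        assert s.percents["a_and_c_only"] == 10.6
        assert s.percents["c_only"] == 7.6

    def test_relation_percents(self):
        records = cohort_from_counts(54, 7, 5, 42)
        agreements = agreements_from_counts(n_equal=49, n_larger=12)
        s = cohort_summary(records, agreements)
        assert s.relation_counts == {"equal": 49, "larger": 12, "smaller": 0}
        assert s.relation_percents["equal"] == 74.2
        assert s.relation_percents["larger"] == 18.2

    def test_duration_crosstab_percents(self):
        """Halo sign split 36 acute / 13 chronic of 66 -> 54.5% vs 19.7%."""
        records = cohort_from_counts(
            n_all_three=49, n_a_c_only=12, n_c_only=5, n_acute=42,
            n_type_b_acute=36,
        )
        s = cohort_summary(records)
        assert s.type_b_by_duration["acute_b"] == 36
        assert s.type_b_by_duration["chronic_b"] == 13
        assert s.percents["type_b_acute"] == 54.5
        assert s.percents["type_b_chronic"] == 19.7
        assert s.chisq_type_b_duration is not None
        assert s.chisq_type_b_duration[1] < 0.05

    def test_no_type_b_cohort(self):
        records = cohort_from_counts(0, 10, 0, 5)
        s = cohort_summary(records)
        assert s.percents["type_b"] == 0.0

    def test_percent_count_consistency(self, rng):
        """Every percent equals 100*count/n within rounding."""
        records = cohort_from_counts(20, 9, 4, 18, n_type_b_acute=15)
        s = cohort_summary(records)
        for key, count in s.counts.items():
            assert abs(s.percents[key] - 100 * count / s.n_eyes) <= 0.05

    def test_empty_cohort_rejected(self):
        with pytest.raises(InsufficientDataError):
            cohort_summary([])

    def test_paired_t_on_matched_areas(self):
        records = cohort_from_counts(3, 0, 0, 2)
        for i, r in enumerate(records):
            r.area_type_a = 12.0 + i
            r.area_hyper_icga = 11.0 + i
        s = cohort_summary(records)
        assert s.paired_t_areas is not None
        assert s.area_stats["type_a_octa"][0] == pytest.approx(13.0)

    def test_round_half_up(self):
        assert round_half_up(92.42424, 1) == 92.4
        assert round_half_up(81.85, 1) == 81.9  # ties go up
        assert round_half_up(74.25, 1) == 74.3


class TestAgreementIO:
    def test_round_trip(self, tmp_path):
        results = agreements_from_counts(2, 1, 1) + [
            AgreementResult("e9", "interobserver_octa", 0.91, 10.0, 10.2)
        ]
        path = tmp_path / "agr.csv"
        write_agreements(results, path)
        loaded = read_agreements(path)
        assert len(loaded) == len(results)
        assert loaded[-1].relation is None
        assert loaded[0].relation == "equal"
        assert loaded[0].jaccard == pytest.approx(results[0].jaccard)


class TestAreaWeightedMean:
    def test_weighting(self):
        results = [
            AgreementResult("e", "octa_vs_icga", 1.0, 3.0, 3.0),
            AgreementResult("e", "octa_vs_icga", 0.0, 1.0, 1.0),
        ]
        assert area_weighted_mean_ji(results) == pytest.approx(6 / 8)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            area_weighted_mean_ji([])
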