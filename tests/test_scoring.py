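"""Severity-criterion scoring: shock indices, component flags, bounds rule."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capscore import (
    AsiMode,
    CRITERIA,
    CriterionName,
    Disposition,
    Severity,
    adjusted_shock_index,
    component_flags,
    score_criterion,
    shock_index,
)

CURB65 = CRITERIA[CriterionName.CURB65]
CRB65 = CRITERIA[CriterionName.CRB65]
CURSI = CRITERIA[CriterionName.CURSI]
CURASI = CRITERIA[CriterionName.CURASI]
CRSI = CRITERIA[CriterionName.CRSI]
CRASI = CRITERIA[CriterionName.CRASI]


class TestShockIndex:
    @pytest.mark.parametrize(
        "hr, sbp, expected",
        [(100, 100, 1.0), (120, 80, 1.5), (56, 208, 56 / 208)],
    )
    def test_ratio(self, hr, sbp, expected):
        assert shock_index(hr, sbp) == pytest.approx(expected)

    @pytest.mark.parametrize("hr, sbp", [(0, 100), (-5, 100), (100, 0)])
    def test_nonpositive_inputs_rejected(self, hr, sbp):
        with pytest.raises(ValueError):
            shock_index(hr, sbp)


class TestAdjustedShockIndex:
    @pytest.mark.parametrize(
        "hr, sbp, temp, mode, expected",
        [
            (110, 100, 38.0, AsiMode.continuous, 1.0),
            (100, 100, 36.0, AsiMode.continuous, 1.0),
            (101, 100, 37.5, AsiMode.continuous, 0.96),
            (101, 100, 37.5, AsiMode.whole_degree, 1.01),
            (110, 100, 38.0, AsiMode.whole_degree, 1.0),
        ],
    )
    def test_deduction(self, hr, sbp, temp, mode, expected):
        assert adjusted_shock_index(hr, sbp, temp, mode) == pytest.approx(expected)

    def test_adjusted_heart_rate_floored_at_zero(self):
        # 40 bpm with a 4-degree fever would go negative without the floor
        assert adjusted_shock_index(30, 100, 41.0, AsiMode.continuous) == 0.0

    @given(
        hr=st.floats(20, 250),
        sbp=st.floats(40, 300),
        temp=st.floats(25, 45),
        mode=st.sampled_from(list(AsiMode)),
    )
    def test_never_exceeds_unadjusted(self, hr, sbp, temp, mode):
        assert adjusted_shock_index(hr, sbp, temp, mode) <= shock_index(hr, sbp)


class TestComponentFlags:
    def test_typical_median_patient_scores_zero(self, make_record):
        # the cohort's median patient: age 61, no confusion, urea 6.65, RR 24
        record = make_record()
        assert component_flags(record, CURB65) == (0, 0, 0, 0, 0)

    @pytest.mark.parametrize(
        "overrides, criterion, expected",
        [
            # boundary semantics pinned exactly as defined
            ({"urea": 7.0}, CURB65, (0, 0, 0, 0, 0)),
            ({"urea": 7.01}, CURB65, (0, 1, 0, 0, 0)),
            ({"resp_rate": 30}, CURB65, (0, 0, 1, 0, 0)),
            ({"resp_rate": 29}, CURB65, (0, 0, 0, 0, 0)),
            ({"sbp": 89.9, "dbp": 70.0}, CURB65, (0, 0, 0, 1, 0)),
            ({"sbp": 90.0, "dbp": 70.0}, CURB65, (0, 0, 0, 0, 0)),
            ({"dbp": 60.0}, CURB65, (0, 0, 0, 1, 0)),
            ({"dbp": 60.5}, CURB65, (0, 0, 0, 0, 0)),
            ({"age": 65}, CURB65, (0, 0, 0, 0, 1)),
            ({"age": 64}, CURB65, (0, 0, 0, 0, 0)),
            ({"heart_rate": 130.0}, CURSI, (0, 0, 0, 0)),  # SI = 1.0 exactly
            ({"heart_rate": 131.0}, CURSI, (0, 0, 0, 1)),
        ],
    )
    def test_boundary_semantics(self, make_record, overrides, criterion, expected):
        record = make_record(**overrides)
        assert component_flags(record, criterion) == expected

    def test_missing_fields_give_indeterminate_flags(self, make_record):
        record = make_record(confusion=None, urea=None)
        assert component_flags(record, CURB65) == (None, None, 0, 0, 0)


class TestScoreCriterion:
    def test_every_component_met(self, make_record):
        record = make_record(
            confusion=True, urea=8.0, resp_rate=32, sbp=85.0, dbp=55.0, age=70
        )
        result = score_criterion(record, CURB65)
        assert result.score == 5
        assert result.severity is Severity.severe
        assert result.disposition is Disposition.complete

    def test_borderline_missing_confusion_excluded(self, make_record):
        # R and B met, age < 65, confusion unknown: CRB-65 in [2, 3] straddles
        # the cutoff of 3, so the class is indeterminate and the patient drops
        record = make_record(confusion=None, resp_rate=32, sbp=85.0, age=50)
        result = score_criterion(record, CRB65)
        assert (result.score_lower, result.score_upper) == (2, 3)
        assert result.severity is Severity.excluded
        assert result.disposition is Disposition.excluded_borderline

    def test_missing_value_cannot_change_class(self, make_record):
        # C, R and age-65 met: CURB-65 lower bound already reaches 3, so the
        # missing urea cannot demote the patient; kept as severe
        record = make_record(confusion=True, urea=None, resp_rate=32, age=70)
        result = score_criterion(record, CURB65)
        assert (result.score_lower, result.score_upper) == (3, 4)
        assert result.severity is Severity.severe
        assert result.disposition is Disposition.allocated_despite_missing

    def test_non_severe_despite_missing(self, make_record):
        record = make_record(urea=None)
        result = score_criterion(record, CURB65)
        assert result.severity is Severity.non_severe
        assert result.disposition is Disposition.allocated_despite_missing

    def test_exhaustive_flag_patterns_match_brute_force(self, make_record):
        """All 2^5 complete CURB-65 patterns agree with a naive re-derivation."""
        realise = {
            "C": {"confusion": True},
            "U": {"urea": 8.0},
            "R": {"resp_rate": 32},
            "B": {"sbp": 85.0, "dbp": 55.0},
            "65": {"age": 70},
        }
        for pattern in itertools.product([0, 1], repeat=5):
            overrides = {}
            for bit, comp in zip(pattern, ["C", "U", "R", "B", "65"]):
                if bit:
                    overrides.update(realise[comp])
            result = score_criterion(make_record(**overrides), CURB65)
            # independent oracle: count the bits, compare to the cutoff
            total = sum(pattern)
            assert result.score == total
            expected = Severity.severe if total >= 3 else Severity.non_severe
            assert result.severity is expected


@st.composite
def complete_records(draw, make_record):
    return make_record(
        patient_id="H1",
        age=draw(st.integers(17, 96)),
        confusion=draw(st.booleans()),
        urea=draw(st.floats(1.0, 30.9)),
        resp_rate=draw(st.integers(10, 40)),
        sbp=draw(st.floats(75.0, 208.0)),
        dbp=draw(st.floats(40.0, 74.0)),
        heart_rate=draw(st.floats(56.0, 170.0)),
        temperature=draw(st.floats(33.4, 40.0)),
    )


class TestInvariants:
    @given(data=st.data())
    @settings(max_examples=200)
    def test_adjusted_criteria_equal_unadjusted_below_37(self, make_record, data):
        """With no fever there is no deduction: CURASI=CURSI, CRASI=CRSI."""
        record = data.draw(complete_records(make_record))
        if record.temperature > 37.0:
            record = record.model_copy(update={"temperature": 36.5})
        for mode in AsiMode:
            for adj, unadj in [(CURASI, CURSI), (CRASI, CRSI)]:
                assert (
                    score_criterion(record, adj, mode).score
                    == score_criterion(record, unadj, mode).score
                )

    @given(data=st.data())
    @settings(max_examples=200)
    def test_complete_records_have_tight_bounds(self, make_record, data):
        record = data.draw(complete_records(make_record))
        for criterion in CRITERIA.values():
            result = score_criterion(record, criterion)
            assert result.score_lower == result.score_upper <= criterion.max_score
            assert result.disposition is Disposition.complete

    @given(data=st.data())
    @settings(max_examples=100)
    def test_worsening_vitals_never_lower_the_score(self, make_record, data):
        """Raising HR/urea/RR or adding confusion, or dropping SBP, is monotone."""
        record = data.draw(complete_records(make_record))
        worse = record.model_copy(
            update={
                "confusion": True,
                "urea": min(60.0, record.urea + 5),
                "resp_rate": min(80, record.resp_rate + 8),
                "sbp": max(record.dbp + 1.0, record.sbp - 20),
                "heart_rate": min(250.0, record.heart_rate + 20),
            }
        )
        for criterion in CRITERIA.values():
            assert (
                score_criterion(worse, criterion).score_lower
                >= score_criterion(record, criterion).score_lower
            )
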