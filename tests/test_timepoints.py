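"""The four-scenario time-point extractor, its validity rules and resolver."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timecourse_miner import SeriesMetadata
from timecourse_miner.timepoints import (
    UNIT_FACTORS,
    TimeValue,
    dedupe_time_values,
    extract_approximate,
    extract_explicit,
    extract_listings,
    extract_title_candidates,
    has_progression,
    normalize_time_unit,
    resolve_series,
    validate_title_candidates,
)


class TestUnitNormalization:
    @pytest.mark.parametrize(
        "token,unit,single",
        [
            ("hr", "hour", False),
            ("h", "hour", True),
            ("D", "day", True),
            ("weeks", "week", False),
            ("min", "minute", False),
            ("stages", "stage-ordinal", False),
            ("yr", "year", False),
        ],
    )
    def test_spellings(self, token, unit, single):
        assert normalize_time_unit(token) == (unit, single)

    def test_non_unit_token(self):
        assert normalize_time_unit("banana") is None


class TestExplicit:
    @pytest.mark.parametrize(
        "text,count",
        [
            ("we profiled 12 time points", 12),
            ("7 developmental stages", 7),
            ("samples at five timepoints", 5),
            ("a time-series across 4 phases", 4),
        ],
    )
    def test_counts(self, text, count):
        assert extract_explicit(text).count == count

    def test_no_leading_number_is_no_call(self):
        assert extract_explicit("time points were sparse") is None

    def test_multiple_statements_err_by_excess(self):
        call = extract_explicit("3 time points early then 8 time points later")
        assert call.count == 8
        assert len(call.evidence) == 2


class TestListings:
    def test_printed_seizure_series_listing_has_six_points(self):
        # 0, 0.25, 1, 3, 6 and 24 h: zero and decimals both count
        call = extract_listings(
            "Samples were harvested at 0, 0.25, 1, 3, 6, and 24 h after treatment."
        )
        assert call.count == 6

    def test_multi_unit_union(self):
        call = extract_listings("harvest at 6, 12 hours and 1, 3, 5 days")
        assert call.count == 5
        canon = sorted(v.canonical_hours for v in call.values)
        assert canon == [6, 12, 24, 72, 120]

    def test_descending_run_rejected(self):
        assert extract_listings("12, 6, 3 hours") is None

    def test_per_value_units_non_decreasing_accepted(self):
        call = extract_listings("latencies of 4 min, 8 min, 9 min and 13.5 min")
        assert call.count == 4

    def test_per_value_units_decreasing_rejected(self):
        assert extract_listings("9 min, 8 min and 4 min") is None

    def test_leading_unit_run(self):
        call = extract_listings("collected on days 0, 3, 7 post infection")
        assert call.count == 3

    def test_duplicate_instants_collapse(self):
        # 24 h and 1 d name the same instant
        call = extract_listings("at 6, 24 hours and 1, 3 days")
        assert call.count == 3

    def test_range_contributes_endpoints(self):
        call = extract_listings("sampled over 0-24 h")
        assert call.count == 2

    def test_plain_prose_numbers_without_units(self):
        assert extract_listings("we studied 3 mice and 5 rats") is None


class TestApproximate:
    @pytest.mark.parametrize("text", ["at early stage and late stage",
                                      "middle age mice", "terminal phase disease"])
    def test_lexicon_hits_have_no_count(self, text):
        call = extract_approximate(text)
        assert call is not None and call.count is None

    def test_evidence_spans(self):
        call = extract_approximate("at early stage and late stage")
        assert call.evidence == ["early stage", "late stage"]

    def test_lexicon_miss(self):
        assert extract_approximate("staged surgery") is None


class TestTitleCandidates:
    def test_single_letter_grid(self):
        cands = extract_title_candidates(["ctrl d1 r1", "ctrl d3 r1", "ctrl d7 r1"])
        assert sorted((c.value.magnitude, c.value.unit) for c in cands) == [
            (1.0, "day"), (3.0, "day"), (7.0, "day")]
        assert all(c.value.single_letter for c in cands)

    def test_no_temporal_tokens(self):
        assert extract_title_candidates(["sample A", "sample B"]) == []

    def test_word_and_abbreviated_units(self):
        cands = extract_title_candidates(["day 1 rep", "10 hr rep"])
        assert sorted((c.value.magnitude, c.value.unit) for c in cands) == [
            (1.0, "day"), (10.0, "hour")]
        assert not any(c.value.single_letter for c in cands)

    def test_positions_recorded(self):
        (cand,) = extract_title_candidates(["ctrl d3 rep"])
        assert cand.title_index == 0
        assert cand.offset == 5
        assert cand.unit_offset == 5


def _make_meta(titles, summary="", design=""):
    return SeriesMetadata("GSE1", summary=summary, overall_design=design,
                          sample_titles=titles)


class TestTitleValidityRules:
    def test_geometric_grid_accepted(self):
        titles = [f"cond d{v} rep1" for v in (1, 2, 4, 8)]
        cands = extract_title_candidates(titles)
        accepted, rejections = validate_title_candidates(cands, _make_meta(titles))
        assert sorted(v.magnitude for v in accepted) == [1, 2, 4, 8]
        assert rejections == []

    def test_rule_i_patient_count_echo_flips_acceptance(self):
        # the same ages accepted with a clean summary are rejected when the
        # summary mentions one of the numbers next to "patients"
        titles = ["patient 45y", "patient 52y"]
        cands = extract_title_candidates(titles)
        clean, _ = validate_title_candidates(cands, _make_meta(titles))
        assert len(clean) == 2
        meta = _make_meta(titles, summary="45 patients enrolled")
        accepted, rejections = validate_title_candidates(cands, meta)
        assert accepted == []
        assert {reason for _, reason in rejections} == {"rule-i"}

    def test_rule_ii_foreign_letter_in_slot_flips_acceptance(self):
        good = ["cond d1 rep1", "cond d2 rep1", "cond d4 rep1"]
        cands = extract_title_candidates(good)
        accepted, _ = validate_title_candidates(cands, _make_meta(good))
        assert len(accepted) == 3
        # same grid, but another title carries a non-time letter in the slot
        bad = good + ["cond x9 rep1"]
        cands = extract_title_candidates(bad)
        accepted, rejections = validate_title_candidates(cands, _make_meta(bad))
        assert accepted == []
        assert {reason for _, reason in rejections} == {"rule-ii"}

    def test_rule_iii_no_progression_flips_acceptance(self):
        titles = [f"cond d{v} rep1" for v in (1, 5, 12)]
        cands = extract_title_candidates(titles)
        accepted, rejections = validate_title_candidates(cands, _make_meta(titles))
        assert accepted == []
        assert {reason for _, reason in rejections} == {"rule-iii"}

    def test_two_values_pass_rule_iii_vacuously(self):
        titles = ["cond d1 rep1", "cond d5 rep1"]
        cands = extract_title_candidates(titles)
        accepted, _ = validate_title_candidates(cands, _make_meta(titles))
        assert len(accepted) == 2

    def test_full_word_units_bypass_rules_i_and_ii(self):
        titles = ["day 45 sample", "day 52 sample"]
        cands = extract_title_candidates(titles)
        meta = _make_meta(titles, summary="45 patients enrolled")
        accepted, _ = validate_title_candidates(cands, meta)
        assert len(accepted) == 2


def _oracle_has_progression(values, rel_tol=1e-6):
    """Exhaustive enumeration over all subsets of size >= 3."""
    vals = sorted(set(values))
    for size in range(3, len(vals) + 1):
        for sub in itertools.combinations(vals, size):
            diffs = [b - a for a, b in zip(sub, sub[1:])]
            if all(math.isclose(d, diffs[0], rel_tol=rel_tol, abs_tol=1e-12)
                   for d in diffs):
                return True
            if all(v > 0 for v in sub):
                ratios = [b / a for a, b in zip(sub, sub[1:])]
                if all(math.isclose(r, ratios[0], rel_tol=rel_tol)
                       for r in ratios):
                    return True
    return False


class TestProgression:
    @pytest.mark.parametrize(
        "values,expected",
        [([0, 3, 6], True), ([1, 2, 4], True), ([1, 5, 12], False),
         ([2, 4], False), ([0, 1, 2, 7, 50], True)],
    )
    def test_known_cases(self, values, expected):
        assert has_progression(values) is expected

    @given(st.sets(st.integers(min_value=0, max_value=30), min_size=0, max_size=8))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, values):
        vals = [float(v) for v in values]
        assert has_progression(vals) == _oracle_has_progression(vals)


class TestDedupe:
    def test_cross_unit_identity(self):
        assert len(dedupe_time_values([TimeValue(24, "hour"), TimeValue(1, "day")])) == 1

    def test_zero_identity_across_units(self):
        assert len(dedupe_time_values([TimeValue(0, "hour"), TimeValue(0, "day")])) == 1

    def test_mixed_units_kept_distinct(self):
        vals = [TimeValue(6, "hour"), TimeValue(12, "hour"), TimeValue(1, "day"),
                TimeValue(3, "day"), TimeValue(5, "day")]
        assert len(dedupe_time_values(vals)) == 5

    def test_stage_ordinals_compare_by_magnitude(self):
        vals = [TimeValue(1, "stage-ordinal"), TimeValue(1, "stage-ordinal"),
                TimeValue(1, "hour")]
        assert len(dedupe_time_values(vals)) == 2


class TestResolve:
    def test_max_policy_prefers_largest_count(self):
        meta = SeriesMetadata(
            "GSE1", summary="we profiled 12 time points",
            sample_titles=["cond d1 r", "cond d2 r", "cond d4 r"])
        result = resolve_series(meta)
        assert result.final_count == 12
        assert result.winning_scenario == "EXPLICIT"

    def test_default_single_time_point(self):
        result = resolve_series(SeriesMetadata("GSE1"))
        assert result.final_count == 1
        assert result.final_values == []

    def test_superseries_excluded(self):
        meta = SeriesMetadata(
            "GSE1",
            summary="This SuperSeries is composed of the SubSeries listed below.")
        result = resolve_series(meta)
        assert result.excluded and result.final_count == 0 and result.calls == []

    def test_err_by_excess_dominates_all_counted_calls(self):
        meta = SeriesMetadata(
            "GSE1",
            summary="harvest at 6, 12 hours and 1, 3, 5 days",
            overall_design="3 time points",
            sample_titles=["cond d1 r", "cond d3 r"])
        result = resolve_series(meta)
        counted = [c.count for c in result.calls if c.count is not None]
        assert result.final_count == max(counted) == 5

    def test_approximate_flag_never_counts(self):
        meta = SeriesMetadata("GSE1", summary="tumors at early stage and late stage")
        result = resolve_series(meta)
        assert result.approximate_flag and result.final_count == 1

    def test_unit_invariance_of_final_count(self):
        # rewriting 24 h as 1 day leaves the resolved count unchanged
        a = resolve_series(SeriesMetadata("G", summary="at 6, 12, 24 hours"))
        b = resolve_series(SeriesMetadata(
            "G", summary="at 6 hours, 12 hours and 1 day"))
        assert a.final_count == b.final_count == 3

    def test_determinism(self):
        meta = SeriesMetadata(
            "GSE1", summary="harvest at 6, 12 hours and 1, 3, 5 days",
            sample_titles=["cond d1 r", "cond d2 r", "cond d4 r"])
        assert resolve_series(meta) == resolve_series(meta)


# --- grammar-based oracle equivalence ---------------------------------------

_SPELLINGS = {
    "second": ["sec", "seconds", "s"],
    "minute": ["min", "minutes"],
    "hour": ["h", "hr", "hrs", "hours"],
    "day": ["d", "day", "days"],
    "week": ["w", "wk", "weeks"],
    "month": ["months", "mo"],
    "year": ["yr", "years", "y"],
}
_VALUE_GRID = [0, 0.25, 0.5, 1, 2, 3, 4, 5, 6, 8, 10, 12, 16, 24, 36, 48, 72]


def _gen_run(rng):
    unit = rng.choice(sorted(_SPELLINGS))
    spelling = rng.choice(_SPELLINGS[unit])
    k = rng.randint(2, 6)
    values = sorted(rng.sample(_VALUE_GRID, k))
    style = rng.choice(["trailing", "leading", "per-value"])
    nums = [f"{v:g}" for v in values]
    if style == "trailing":
        body = ", ".join(nums[:-1]) + (", and " if rng.random() < 0.5 else ", ") + nums[-1]
        text = f"{body} {spelling}"
    elif style == "leading":
        text = f"{spelling} " + ", ".join(nums)
    else:
        text = ", ".join(f"{n} {spelling}" for n in nums[:-1]) + f" and {nums[-1]} {spelling}"
    return text, [(v, unit) for v in values], style


def _gen_listing_sentence(rng):
    runs = [_gen_run(rng) for _ in range(rng.randint(1, 2))]
    parts, pairs = [], []
    prev_style = None
    for i, (text, run_pairs, style) in enumerate(runs):
        if i > 0:
            # a bare "and" can splice two adjacent lists into one (possibly
            # non-monotonic) list; an anchor word keeps multi-lists apart
            splice = style == "per-value" or (
                prev_style == "leading" and style == "trailing")
            parts.append(" and at " if splice else " and ")
        parts.append(text)
        pairs.extend(run_pairs)
        prev_style = style
    return "Samples were harvested at " + "".join(parts) + " after treatment.", pairs


def _oracle_count(pairs):
    """Distinct canonical values, independent of any extraction regex."""
    canon = {round(v * UNIT_FACTORS[u], 9) for v, u in pairs}
    return len(canon)


def test_listing_extractor_matches_bruteforce_oracle_on_generated_grammar():
    """On >=1000 grammar-generated listing sentences the extractor's count
    equals brute-force enumeration of distinct canonical values."""
    rng = random.Random(20240901)
    mismatches = []
    for _ in range(1200):
        sentence, pairs = _gen_listing_sentence(rng)
        expected = _oracle_count(pairs)
        call = extract_listings(sentence)
        got = call.count if call else 0
        if got != expected:
            mismatches.append((sentence, expected, got))
    assert not mismatches, mismatches[:5]
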