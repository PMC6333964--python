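"""Rule-based extraction of time-point structure from series metadata.

A time-course series states its sampling times in free text in one of four
ways, each handled by its own extractor:

1. EXPLICIT — an explicit count: "12 time points", "7 developmental stages".
2. LISTING — an enumeration of times: "harvest at 6, 12 hours and 1, 3, 5
   days"; valid only when a bare-number run is strictly ascending, or when
   every number carries its own unit and the run is non-decreasing after
   conversion to canonical hours.
3. APPROXIMATE — qualitative phrases ("early stage", "middle age") that
   flag temporality without a countable value.
4. SAMPLE_TITLES — number+unit tokens in sample titles ("day 1", "d1",
   "10 hr", "10h"), subject to three validity rules that discard patient
   ages, sample counts echoed in the summary, and candidate sets with no
   arithmetic- or geometric-progression backbone.

The resolver is deliberately biased to err by excess: when scenarios
disagree it keeps the largest validated count, because spurious extra time
points are easy to discard downstream while missed ones are not.
"""

from __future__ import annotations

import math
import re
import unicodedata
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .geo_io import SeriesMetadata, is_superseries

__all__ = [
    "TimeValue",
    "TimePointCall",
    "TitleCandidate",
    "SeriesTimeResult",
    "EngineConfig",
    "UNIT_FACTORS",
    "normalize_time_unit",
    "extract_explicit",
    "extract_listings",
    "extract_approximate",
    "extract_title_candidates",
    "validate_title_candidates",
    "has_progression",
    "dedupe_time_values",
    "resolve_series",
    "format_time_value",
]

# Canonical unit factors in hours.  Months are fixed at 30 days and years
# at 365 days so that canonical conversion is deterministic.
UNIT_FACTORS: dict[str, float] = {
    "second": 1.0 / 3600.0,
    "minute": 1.0 / 60.0,
    "hour": 1.0,
    "day": 24.0,
    "week": 168.0,
    "month": 720.0,
    "year": 8760.0,
}

STAGE_ORDINAL = "stage-ordinal"

# Unit spelling -> canonical unit.  Single-letter spellings are additionally
# flagged because the sample-title validity rules only police those.
_UNIT_SPELLINGS: dict[str, str] = {}
for _unit, _spellings in {
    "second": ["s", "sec", "secs", "second", "seconds"],
    "minute": ["min", "mins", "minute", "minutes"],
    "hour": ["h", "hr", "hrs", "hour", "hours"],
    "day": ["d", "day", "days"],
    "week": ["w", "wk", "wks", "week", "weeks"],
    "month": ["m", "mo", "mos", "month", "months"],
    "year": ["y", "yr", "yrs", "year", "years"],
    STAGE_ORDINAL: ["stage", "stages", "passage", "passages"],
}.items():
    for _sp in _spellings:
        _UNIT_SPELLINGS[_sp] = _unit

#: Letters that may legitimately denote a time unit in sample titles;
#: any other letter in the same title slot marks the slot as non-temporal.
TIME_UNIT_LETTERS = frozenset("shdwmy")


def normalize_time_unit(token: str) -> Optional[tuple[str, bool]]:
    """Map a unit spelling to ``(canonical_unit, is_single_letter)``.

    Case-insensitive; returns ``None`` for non-unit tokens.
    """
    lower = token.strip().lower()
    unit = _UNIT_SPELLINGS.get(lower)
    if unit is None:
        return None
    return unit, len(lower) == 1


@dataclass(frozen=True)
class TimeValue:
    """A magnitude+unit pair with its canonical form.

    ``canonical_hours`` is ``magnitude * factor(unit)`` for temporal units
    and ``None`` for stage ordinals, which compare by magnitude alone.
    """

    magnitude: float
    unit: str
    source_text: str = ""
    single_letter: bool = False

    @property
    def canonical_hours(self) -> Optional[float]:
        factor = UNIT_FACTORS.get(self.unit)
        return None if factor is None else self.magnitude * factor

    def same_instant(self, other: "TimeValue", rel_tol: float = 1e-9) -> bool:
        a, b = self.canonical_hours, other.canonical_hours
        if a is None or b is None:
            if a is not None or b is not None:
                return False
            return math.isclose(self.magnitude, other.magnitude,
                                rel_tol=rel_tol, abs_tol=1e-12)
        return math.isclose(a, b, rel_tol=rel_tol, abs_tol=1e-12)


@dataclass(frozen=True)
class TitleCandidate:
    """A time-value candidate found in a sample title, with position.

    ``unit_offset`` is the character offset of the unit token inside the
    title; the slot-consistency rule compares this offset across titles.
    """

    value: TimeValue
    title_index: int
    offset: int
    unit_offset: int


@dataclass
class TimePointCall:
    """One extraction scenario's verdict on one text field."""

    scenario: str  # EXPLICIT | LISTING | APPROXIMATE | SAMPLE_TITLES
    count: Optional[int]
    values: list[TimeValue] = field(default_factory=list)
    field_source: str = "summary"
    evidence: list[str] = field(default_factory=list)


@dataclass
class SeriesTimeResult:
    """Resolved time-point structure for one series, with provenance."""

    accession: str
    final_count: int
    final_values: list[TimeValue] = field(default_factory=list)
    calls: list[TimePointCall] = field(default_factory=list)
    excluded: bool = False
    approximate_flag: bool = False
    winning_scenario: str = ""
    rejections: list[tuple[TimeValue, str]] = field(default_factory=list)


@dataclass
class EngineConfig:
    """Tunable knobs of the extraction rules (documented defaults)."""

    keyword_window: int = 2
    count_keywords: tuple[str, ...] = (
        "sample", "samples", "patient", "patients", "subject", "subjects",
    )
    progression_rel_tol: float = 1e-6
    dedupe_rel_tol: float = 1e-9


DEFAULT_CONFIG = EngineConfig()

_NUM = r"\d+(?:\.\d+)?"
_NUMBER_WORDS = {
    w: i
    for i, w in enumerate(
        "one two three four five six seven eight nine ten eleven twelve "
        "thirteen fourteen fifteen sixteen seventeen eighteen nineteen twenty".split(),
        start=1,
    )
}

# Longest spellings first so e.g. "hr" wins over "h" in alternation.
_UNIT_RE = "|".join(sorted(map(re.escape, _UNIT_SPELLINGS), key=len, reverse=True))

_EXPLICIT_KEYWORDS = (
    r"time[\s-]?points?|time[\s-]?series|developmental\s+stages?|stages?|phases?"
)
_EXPLICIT_RE = re.compile(
    rf"\b({_NUM}|{'|'.join(_NUMBER_WORDS)})\s+({_EXPLICIT_KEYWORDS})\b",
    re.IGNORECASE,
)

_APPROX_RE = re.compile(
    r"\b(early|middle|late|terminal)\s+(stage|phase|age|time\s+point)s?\b",
    re.IGNORECASE,
)

_SEP = r"\s*(?:,\s*(?:and\s+)?|and\s+)"
# Bare-number run with one trailing unit: "0, 0.25, 1, 3, 6, and 24 h"
_RUN_TRAILING = re.compile(
    rf"\b({_NUM})((?:{_SEP}{_NUM})+)[\s-]*({_UNIT_RE})\b", re.IGNORECASE
)
# Bare-number run with one leading unit: "days 0, 3, 7"
_RUN_LEADING = re.compile(
    rf"\b({_UNIT_RE})\s+({_NUM})((?:{_SEP}{_NUM})+)\b", re.IGNORECASE
)
# Per-value-unit run: "4 min, 8 min, 9 min and 13.5 min"
_RUN_PER_UNIT = re.compile(
    rf"\b({_NUM})[\s-]*({_UNIT_RE})((?:{_SEP}{_NUM}[\s-]*(?:{_UNIT_RE}))+)\b",
    re.IGNORECASE,
)
_NUM_RE = re.compile(_NUM)
_NUM_UNIT_RE = re.compile(rf"({_NUM})[\s-]*({_UNIT_RE})\b", re.IGNORECASE)

# Title tokens: number+unit ("10 hr", "10h") and unit+number ("day 1", "d1").
_TITLE_NUM_UNIT = re.compile(rf"\b({_NUM})\s*({_UNIT_RE})\b", re.IGNORECASE)
_TITLE_UNIT_NUM = re.compile(rf"\b({_UNIT_RE})\s*({_NUM})\b", re.IGNORECASE)

_RANGE_RE = re.compile(rf"\b({_NUM})\s*[-–]\s*({_NUM})(?=\s*(?:{_UNIT_RE})\b)",
                       re.IGNORECASE)


def _normalize_text(text: str) -> str:
    """NFC-normalise, map en-dashes to hyphens, expand ranges to endpoints."""
    text = unicodedata.normalize("NFC", text).replace("–", "-")
    # "0-24 h" contributes only its endpoints, rendered as a two-element list
    return _RANGE_RE.sub(lambda m: f"{m.group(1)}, {m.group(2)}", text)


def _parse_number(token: str) -> float:
    word = _NUMBER_WORDS.get(token.lower())
    return float(word) if word is not None else float(token)


# --- Scenario 1: explicit counts -------------------------------------------


def extract_explicit(text: str, field_source: str = "summary") -> Optional[TimePointCall]:
    """Find explicit statements of the number of time points or stages.

    Accepts numerals and the number words one..twenty.  When several
    statements occur, the largest count wins (err-by-excess) and every
    matched span is kept as evidence.
    """
    text = _normalize_text(text)
    best: Optional[int] = None
    spans: list[str] = []
    for m in _EXPLICIT_RE.finditer(text):
        n = int(round(_parse_number(m.group(1))))
        spans.append(m.group(0))
        if best is None or n > best:
            best = n
    if best is None:
        return None
    return TimePointCall("EXPLICIT", best, [], field_source, spans)


# --- Scenario 2: listings ---------------------------------------------------


def _mask(text: str, span: tuple[int, int]) -> str:
    s, e = span
    return text[:s] + " " * (e - s) + text[e:]


def extract_listings(text: str, field_source: str = "summary",
                     config: EngineConfig = DEFAULT_CONFIG) -> Optional[TimePointCall]:
    """Find listings of time values in a summary or design paragraph.

    Three listing shapes are recognised: a run where every number carries
    its own unit (accepted when non-decreasing in canonical hours), and
    bare-number runs with one unit before or after the run (accepted only
    when strictly ascending).  Several accepted runs union into one call;
    the count is the number of distinct canonical values.
    """
    text = _normalize_text(text)
    values: list[TimeValue] = []
    spans: list[str] = []

    # Per-value-unit runs first; their spans are masked so the bare-number
    # patterns cannot re-match fragments of them.
    for m in list(_RUN_PER_UNIT.finditer(text)):
        run = [
            TimeValue(float(num), unit, source_text=f"{num} {tok}",
                      single_letter=single)
            for num, tok, (unit, single) in (
                (g[0], g[1], normalize_time_unit(g[1]))
                for g in _NUM_UNIT_RE.findall(m.group(0))
            )
        ]
        canon = [v.canonical_hours if v.canonical_hours is not None else v.magnitude
                 for v in run]
        if len(run) >= 2 and all(b >= a for a, b in zip(canon, canon[1:])):
            values.extend(run)
            spans.append(m.group(0))
        text = _mask(text, m.span())

    for pattern, unit_group, nums_groups in (
        (_RUN_TRAILING, 3, (1, 2)),
        (_RUN_LEADING, 1, (2, 3)),
    ):
        for m in list(pattern.finditer(text)):
            norm = normalize_time_unit(m.group(unit_group))
            if norm is None:
                continue
            unit, single = norm
            nums = []
            for g in nums_groups:
                nums.extend(float(tok) for tok in _NUM_RE.findall(m.group(g) or ""))
            if len(nums) >= 2 and all(b > a for a, b in zip(nums, nums[1:])):
                values.extend(
                    TimeValue(n, unit, source_text=m.group(0), single_letter=single)
                    for n in nums
                )
                spans.append(m.group(0))
            text = _mask(text, m.span())

    if not values:
        return None
    deduped = dedupe_time_values(values, rel_tol=config.dedupe_rel_tol)
    return TimePointCall("LISTING", len(deduped), deduped, field_source, spans)


# --- Scenario 3: approximate statements -------------------------------------


def extract_approximate(text: str, field_source: str = "summary") -> Optional[TimePointCall]:
    """Flag qualitative temporal phrases ("early stage", "middle age").

    These mark a series as temporally structured but never contribute a
    numeric count; the call's count is ``None``.
    """
    spans = [m.group(0) for m in _APPROX_RE.finditer(_normalize_text(text))]
    if not spans:
        return None
    return TimePointCall("APPROXIMATE", None, [], field_source, spans)


# --- Scenario 4: sample titles ----------------------------------------------


def extract_title_candidates(titles: Sequence[str]) -> list[TitleCandidate]:
    """Collect number+unit / unit+number tokens from sample titles.

    Every candidate keeps its title index and character offsets; duplicates
    across titles are kept because the validity rules need positional
    context.
    """
    out: list[TitleCandidate] = []
    for idx, title in enumerate(titles):
        text = _normalize_text(title)
        taken: list[tuple[int, int]] = []

        def overlaps(span: tuple[int, int]) -> bool:
            return any(s < span[1] and span[0] < e for s, e in taken)

        for pattern, num_first in ((_TITLE_NUM_UNIT, True), (_TITLE_UNIT_NUM, False)):
            for m in pattern.finditer(text):
                if overlaps(m.span()):
                    continue
                num_tok, unit_tok = (m.group(1), m.group(2)) if num_first else (m.group(2), m.group(1))
                norm = normalize_time_unit(unit_tok)
                if norm is None:
                    continue
                unit, single = norm
                unit_offset = m.start(2) if num_first else m.start(1)
                out.append(
                    TitleCandidate(
                        TimeValue(float(num_tok), unit, source_text=m.group(0),
                                  single_letter=single),
                        title_index=idx,
                        offset=m.start(),
                        unit_offset=unit_offset,
                    )
                )
                taken.append(m.span())
    return out


def _count_context_numbers(meta: SeriesMetadata, window: int,
                           keywords: Iterable[str]) -> set[float]:
    """Numbers within ``window`` tokens of sample/patient-count keywords."""
    keyword_set = {k.lower() for k in keywords}
    found: set[float] = set()
    for text in (meta.summary, meta.overall_design):
        tokens = re.findall(r"[A-Za-z]+|\d+(?:\.\d+)?", _normalize_text(text))
        for i, tok in enumerate(tokens):
            if tok.lower() in keyword_set:
                lo, hi = max(0, i - window), min(len(tokens), i + window + 1)
                for other in tokens[lo:hi]:
                    if re.fullmatch(_NUM, other):
                        found.add(float(other))
    return found


def validate_title_candidates(
    candidates: Sequence[TitleCandidate],
    meta: SeriesMetadata,
    config: EngineConfig = DEFAULT_CONFIG,
) -> tuple[list[TimeValue], list[tuple[TimeValue, str]]]:
    """Apply the three sample-title validity rules.

    Rule i   — single-letter candidates are all false time points if any of
               their magnitudes is mentioned near "samples"/"patients"/
               "subjects" in the summary or overall design (a sample or
               patient count, not a time).
    Rule ii  — single-letter candidates are false if a letter outside the
               time-unit alphabet occupies the same character slot in
               another title (the slot encodes something other than time).
    Rule iii — a deduped set of ≥3 distinct values must contain a 3-term
               arithmetic or geometric progression, else all candidates are
               rejected (real sampling schedules are regular).

    Rules i–ii police only single-letter units; full-word units are
    trusted.  Returns ``(accepted_deduped_values, rejections)`` where each
    rejection is ``(value, rule_id)``.
    """
    rejections: list[tuple[TimeValue, str]] = []
    singles = [c for c in candidates if c.value.single_letter]
    fulls = [c for c in candidates if not c.value.single_letter]

    # rule i: magnitude collides with a sample/patient count in the text
    if singles:
        context = _count_context_numbers(meta, config.keyword_window,
                                         config.count_keywords)
        if any(c.value.magnitude in context for c in singles):
            rejections.extend((c.value, "rule-i") for c in singles)
            singles = []

    # rule ii: a non-time letter occupies the same slot in another title
    if singles:
        titles = meta.sample_titles
        bad_slots: set[int] = set()
        for c in singles:
            for j, other in enumerate(titles):
                if j == c.title_index or len(other) <= c.unit_offset:
                    continue
                ch = other[c.unit_offset].lower()
                if ch.isalpha() and ch not in TIME_UNIT_LETTERS:
                    bad_slots.add(c.unit_offset)
                    break
        if bad_slots:
            hit = [c for c in singles if c.unit_offset in bad_slots]
            rejections.extend((c.value, "rule-ii") for c in hit)
            singles = [c for c in singles if c.unit_offset not in bad_slots]

    survivors = [c.value for c in singles] + [c.value for c in fulls]
    deduped = dedupe_time_values(survivors, rel_tol=config.dedupe_rel_tol)

    # rule iii: need an AP/GP backbone once ≥3 distinct values remain
    if len(deduped) >= 3:
        canon = [v.canonical_hours if v.canonical_hours is not None else v.magnitude
                 for v in deduped]
        if not has_progression(canon, rel_tol=config.progression_rel_tol):
            rejections.extend((v, "rule-iii") for v in deduped)
            return [], rejections
    return deduped, rejections


def has_progression(values: Iterable[float], rel_tol: float = 1e-6) -> bool:
    """True iff some ≥3-value subset is an arithmetic or geometric progression.

    Any AP or GP of length ≥3 contains a 3-term one, so scanning the 3-value
    subsets of the sorted distinct values is exhaustive and exact for every
    input size.  GP membership requires strictly positive values.
    """
    vals = sorted(set(values))
    if len(vals) < 3:
        return False
    for a, b, c in combinations(vals, 3):
        if math.isclose(b - a, c - b, rel_tol=rel_tol, abs_tol=1e-12):
            return True
        if a > 0 and math.isclose(b * b, a * c, rel_tol=rel_tol, abs_tol=1e-12):
            return True
    return False


def dedupe_time_values(values: Sequence[TimeValue], rel_tol: float = 1e-9) -> list[TimeValue]:
    """Collapse values naming the same instant (24 h ≡ 1 day).

    Temporal values compare by canonical hours within ``rel_tol``; stage
    ordinals compare by magnitude.  The first-seen representative is kept,
    in first-seen order.
    """
    kept: list[TimeValue] = []
    for v in values:
        if not any(v.same_instant(k, rel_tol=rel_tol) for k in kept):
            kept.append(v)
    return kept


def format_time_value(v: TimeValue) -> str:
    mag = f"{v.magnitude:g}"
    return f"{mag} {v.unit}"


# --- Resolution --------------------------------------------------------------

_SCENARIO_RANK = {"EXPLICIT": 0, "LISTING": 1, "SAMPLE_TITLES": 2}
_FIELD_RANK = {"summary": 0, "overall_design": 1, "sample_titles": 2}


def resolve_series(meta: SeriesMetadata,
                   config: EngineConfig = DEFAULT_CONFIG) -> SeriesTimeResult:
    """Run all four scenarios on one series and resolve a final count.

    Super-series are excluded (count 0).  Otherwise the final count is the
    maximum over all counted calls — the err-by-excess policy — with ties
    broken by scenario precedence (explicit > listing > titles) and field
    precedence (summary > overall design) when choosing which call supplies
    the final values.  A series with no counted call is a single-time-point
    series (count 1).  Deterministic: a pure function of the metadata.
    """
    if is_superseries(meta):
        return SeriesTimeResult(meta.accession, final_count=0, excluded=True)

    calls: list[TimePointCall] = []
    for field_source, text in (("summary", meta.summary),
                               ("overall_design", meta.overall_design)):
        for extractor in (extract_explicit, extract_approximate):
            call = extractor(text, field_source)
            if call is not None:
                calls.append(call)
        call = extract_listings(text, field_source, config)
        if call is not None:
            calls.append(call)

    rejections: list[tuple[TimeValue, str]] = []
    candidates = extract_title_candidates(meta.sample_titles)
    if candidates:
        accepted, rejections = validate_title_candidates(candidates, meta, config)
        if accepted:
            calls.append(
                TimePointCall("SAMPLE_TITLES", len(accepted), accepted,
                              "sample_titles",
                              [v.source_text for v in accepted])
            )

    counted = [c for c in calls if c.count is not None]
    approximate_flag = any(c.scenario == "APPROXIMATE" for c in calls)
    if not counted:
        return SeriesTimeResult(meta.accession, final_count=1, calls=calls,
                                approximate_flag=approximate_flag,
                                rejections=rejections)

    best = min(
        counted,
        key=lambda c: (-c.count, _SCENARIO_RANK.get(c.scenario, 9),
                       _FIELD_RANK.get(c.field_source, 9)),
    )
    return SeriesTimeResult(
        meta.accession,
        final_count=best.count,
        final_values=list(best.values),
        calls=calls,
        approximate_flag=approximate_flag,
        winning_scenario=best.scenario,
        rejections=rejections,
    )
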