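# Methods

## Scope and model

The package treats time-point identification as deterministic rule-based
information extraction, not statistical learning: every decision is a
pure function of the series' metadata text, so the same input always
yields the same record. The underlying assumptions are that (a) a
time-course series almost always states its design in one of four
surface forms — an explicit count, an enumerated listing, a qualitative
temporal phrase, or number+unit tokens in sample titles — and (b) when
forms disagree, over-counting is the cheaper error, because a user
filtering for "≥ 8 time points" can discard a false positive in seconds
while a false negative is lost. The resolver therefore takes the
maximum over all validated counts ("err by excess"); maximum is the
least aggressive policy consistent with that preference.

## Canonicalisation

Time values are compared in canonical hours with fixed factors: second
1/3600, minute 1/60, hour 1, day 24, week 168, month 720 (30-day
months), year 8760. Calendar months and years are irregular; fixing
them keeps deduplication deterministic, and sub-month schedules — the
overwhelming case in expression time courses — are unaffected. Two
values are the same instant when their canonical hours agree within a
relative tolerance of 1e-9 (so `24 h ≡ 1 day`, `0 h ≡ 0 d`). Stage and
passage ordinals have no canonical hours and compare by magnitude.
Decimal magnitudes are parsed (0.25 h); vulgar fractions ("1/2") are
not. Text is NFC-normalised, en-dashes become hyphens, and a range like
"0–24 h" contributes only its endpoints.

## Listing validity

Bare-number runs with a single unit (before or after the run) must be
*strictly* ascending — descending or shuffled digit runs are almost
never sampling schedules. Runs where each number carries its own unit
need only be *non-decreasing in canonical hours*, since unit changes
mid-list ("45, 90 min, 2 h") legitimately repeat boundary instants.
Several valid runs union, and the reported count is the number of
distinct canonical values in the union.

## Sample-title rules

Rules (i) and (ii) police only single-letter units (`d3`, `45y`);
full-word units ("day 3") are trusted. Rule (i) uses a 2-token window
around the keywords {sample(s), patient(s), subject(s)} — wide enough
for "45 patients enrolled" and "enrolled 45 patients", narrow enough
not to reach across clauses; both window and vocabulary are
configurable. Rule (ii) compares the character slot of the unit letter
across titles; any letter outside `{s,h,d,w,m,y}` in that slot in
another title marks the slot non-temporal. Rule (iii) requires a 3-term
arithmetic or geometric progression among ≥3 distinct values (relative
tolerance 1e-6); sets of ≤2 values pass vacuously, a 2-term progression
being degenerate. The progression test scans all 3-value subsets of the
sorted distinct values: any AP or GP of length ≥3 contains a 3-term
one, so this is exhaustive and exact at every input size, and at the
≤ tens of values a title grid can yield it is effectively free.

Known, deliberate failure mode: durations that are *not* sampling times
— treatment latencies in minutes, recovery times — are
indistinguishable from schedules at the surface level and are extracted
anyway; this class of over-count is retained by design (err by excess)
rather than patched with brittle topic rules.

## Resolution and ties

Counted calls compete by count; on ties the final values come from the
higher-precedence scenario (explicit > listing > sample titles) and
then field (summary > overall design). Precedence affects only which
call's values are reported, never the count. Approximate phrases set a
flag but no count — there is no defensible mapping from "early and late
stage" to a number. A series with no counted call is reported as one
time point; super-series are excluded with count 0.

## Disease tagging

Tagging is dictionary matching against DO names and EXACT/RELATED
synonyms: greedy longest-match over word boundaries, case-insensitive,
plural→singular fallback on the phrase's last word, nested shorter
matches suppressed, surface forms under 3 characters and bare stop
words excluded, each DOID reported once per series from the
highest-precedence field. This is a transparent, dependency-light
design choice: it trades the recall of a full concept-mapping engine
(word-sense disambiguation, derivational variants) for exactness and
auditability — every tag points at a verbatim span. Fuzzy matching is
deliberately absent. Hierarchy metrics use breadth-first shortest
`is_a` paths; obsolete terms detached from the hierarchy report
distance −1. The bundled `mini_do.obo` is a synthetic ~30-term snapshot
whose DOIDs and placement follow the public Human Disease Ontology;
real analyses should supply `doid.obo`.

## Synthetic corpus

The generator emulates the metadata structure the extractor faces: a
200-series corpus stratified 159/33/8 across true counts {1, 2–7
uniform, 8–15 uniform}, schedules drawn as APs or GPs on fixed integer
grids with units in {hour, day, week}, rendered through an explicit
sentence, a listing sentence (trailing-unit or per-value-unit), a
sample-title grid (`cond d3 rep1`), or a mixture. Confounders are
injected per series at default rate 0.15 each — patient ages in titles,
minute-valued latency sentences (multi-time-point series only), and
sample-count echoes — high enough that a 200-series corpus reliably
contains each failure mode, low enough that they stay the exception, as
in real metadata. An `out_of_grammar_rate` (default 0) re-renders
listings with number words, which the extractor does not parse,
producing controlled under-counts that exercise the ±1 metric. All
randomness flows from one seeded `random.Random`, so a spec is
byte-reproducible across platforms.

What the corpus does *not* model: real GEO vocabulary and topic
diversity, typos, MINiML structure, multi-language text, or schedules
that are neither APs nor GPs. Accuracy on this corpus therefore
measures rule/grammar correctness and confounder handling, not
real-world recall; the two printed-example behaviours (the six-point
listing; ages mistaken for times) are the anchors tying it to real
failure cases.

## Evaluation

Exact accuracy counts |pred − truth| = 0; within-±1 accuracy counts
|pred − truth| ≤ 1, absorbing the baseline-time-point ambiguity that
makes even human curators disagree by one. Strata are assigned by the
true count: 1; 2–7 inclusive; over 7 (≥ 8). Per-stratum error rate is
the fraction of that stratum beyond ±1. Excluded super-series are
dropped from scoring with a logged count.

## Defaults and configuration

All tunables live in `AppConfig` and the shipped
`data/default_config.yaml` (loading it reproduces the built-in
defaults): unit factors, the rule-(i) keyword window (2) and vocabulary,
progression tolerance (1e-6), dedupe tolerance (1e-9), ontology path,
output format, log level, seed (42). Rejections are logged with their
rule id and evidence span.

## Limitations

- No full temporal-expression normalisation (calendar dates, clock
  times, "every 4 h for 3 days" arithmetic).
- Minute-valued non-schedule durations are over-counted by design (see
  above).
- Number words are parsed in explicit counts (one–twenty) but not in
  listings.
- The dictionary tagger cannot find diseases mentioned only by
  abbreviations shorter than 3 characters or by surface forms absent
  from DO synonyms.
- Sample grouping by patient/treatment, which could disambiguate ages
  from times, is out of scope: GEO metadata does not encode it.
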