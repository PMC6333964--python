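"""Synthetic GEO-like series metadata with known time-point ground truth.

Extraction accuracy on real GEO series can only be measured against
manual curation; this generator fabricates series whose metadata mimics
the statistical structure of GEO free text — explicit time-point
statements, ascending listings with units, sample-title grids like
"cond d3 rep1" — while recording the true sampling schedule, so accuracy
is measurable without any download.

The generator also injects, at configurable rates, the confounders that
drive real extraction failures: patient ages in sample titles (mistakable
for time values), treatment latency durations in minutes mixed into the
summary, and sample counts echoed in the text.  The default corpus has
200 series stratified 159 / 33 / 8 across true counts {1, 2–7, >7},
mirroring a manually curated evaluation set of that shape.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

from .geo_io import SeriesMetadata
from .timepoints import TimeValue, format_time_value

__all__ = ["CorpusSpec", "SyntheticSeries", "generate_series", "generate_corpus",
           "write_corpus", "render_soft", "CONFOUNDERS"]

CONFOUNDERS = ("patient-age-in-title", "latency-duration-in-text", "sample-count-echo")

_SINGLE_LETTER = {"hour": "h", "day": "d", "week": "w"}
_ORGANISMS = ("Homo sapiens", "Mus musculus", "Rattus norvegicus")
_TISSUES = ("liver", "whole blood", "hippocampus", "skeletal muscle",
            "primary fibroblasts", "lung epithelium")
_DISEASES = ("influenza", "prostate cancer", "breast cancer", "asthma",
             "type 2 diabetes mellitus", "epilepsy", "hypertension")
_NUMBER_WORDS = (
    "zero one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen".split()
)


@dataclass
class CorpusSpec:
    """Conditions under which a synthetic corpus is drawn.

    ``strata_weights`` are the proportions of series with true counts 1,
    2–7 and over 7; ``scenario_mix`` governs how multi-time-point series
    express their schedule; ``confounder_rates`` are per-series injection
    probabilities.  ``out_of_grammar_rate`` is the chance that a listing
    series phrases its schedule in a form outside the extractor's declared
    grammar (number words), exercising the within-±1 metric.  The seed
    fully determines the corpus.
    """

    n_series: int = 200
    strata_weights: dict[str, float] = dc_field(
        default_factory=lambda: {"1": 159 / 200, "2-7": 33 / 200, ">7": 8 / 200}
    )
    scenario_mix: dict[str, float] = dc_field(
        default_factory=lambda: {
            "EXPLICIT": 0.25, "LISTING": 0.35, "SAMPLE_TITLES": 0.25, "mixed": 0.15,
        }
    )
    confounder_rates: dict[str, float] = dc_field(
        default_factory=lambda: {name: 0.15 for name in CONFOUNDERS}
    )
    out_of_grammar_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name, weights in (("strata_weights", self.strata_weights),
                              ("scenario_mix", self.scenario_mix)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total!r})")
        for name, rate in self.confounder_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"confounder rate {name}={rate} outside [0, 1]")


@dataclass
class SyntheticSeries:
    """One fabricated series with its recorded ground truth."""

    meta: SeriesMetadata
    truth_count: int
    truth_values: list[TimeValue] = dc_field(default_factory=list)
    confounders: list[str] = dc_field(default_factory=list)
    scenario: str = ""
    out_of_grammar: bool = False


def _draw_schedule(rng: random.Random, k: int) -> tuple[list[float], str]:
    """An AP or GP of k distinct values with a unit, from fixed grids."""
    unit = rng.choice(("hour", "day", "week"))
    if rng.random() < 0.3 and k <= 8:
        start = rng.choice((1, 2, 3))
        values = [float(start * 2 ** i) for i in range(k)]
    else:
        start = rng.choice((0, 1, 2))
        step = rng.choice((1, 2, 3, 4, 6, 8, 12))
        values = [float(start + i * step) for i in range(k)]
    return values, unit


def _fmt(v: float) -> str:
    return f"{v:g}"


def _render_listing(rng: random.Random, values: list[float], unit: str,
                    out_of_grammar: bool) -> str:
    plural = unit if values[-1] == 1 else unit + "s"
    if out_of_grammar:
        words = [
            _NUMBER_WORDS[int(v)] if float(v).is_integer() and v < 16 else _fmt(v)
            for v in values
        ]
        body = ", ".join(words[:-1]) + " and " + words[-1]
        return f"Samples were collected at {body} {plural} after exposure."
    if rng.random() < 0.35:
        each = [f"{_fmt(v)} {unit if v == 1 else unit + 's'}" for v in values]
        body = ", ".join(each[:-1]) + " and " + each[-1]
    else:
        nums = [_fmt(v) for v in values]
        body = ", ".join(nums[:-1]) + ", and " + nums[-1] + " " + plural
    return f"Samples were harvested at {body} after treatment."


def generate_series(
    spec: CorpusSpec,
    stratum: str,
    rng: random.Random,
    accession: str,
) -> SyntheticSeries:
    """Fabricate one series for a stratum; ground truth is by construction."""
    organism = rng.choice(_ORGANISMS)
    tissue = rng.choice(_TISSUES)
    disease = rng.choice(_DISEASES) if rng.random() < 0.5 else ""
    subject = disease if disease else "untreated control"
    title = f"Expression profiling of {organism} {tissue} ({subject})"
    summary_parts = [
        f"Transcriptional profiling of {tissue} from {organism} was performed"
        f" to study {subject}."
    ]
    design_parts = []
    confounders: list[str] = []
    out_of_grammar = False

    if stratum == "1":
        truth_count, values, unit, scenario = 1, [], "hour", "SINGLE"
        n_reps = rng.randint(4, 8)
        titles = [f"{subject.split()[0]} replicate_{r}" for r in range(1, n_reps + 1)]
        design_parts.append("All samples were collected under identical conditions.")
    else:
        truth_count = rng.randint(2, 7) if stratum == "2-7" else rng.randint(8, 15)
        values, unit = _draw_schedule(rng, truth_count)
        scenario = _weighted_choice(rng, spec.scenario_mix)
        titles = []
        if scenario in ("EXPLICIT", "mixed"):
            summary_parts.append(
                f"Gene expression was profiled at {truth_count} time points"
                " after stimulation."
            )
        if scenario in ("LISTING", "mixed"):
            out_of_grammar = (scenario == "LISTING"
                              and rng.random() < spec.out_of_grammar_rate)
            target = design_parts if scenario == "mixed" else summary_parts
            target.append(_render_listing(rng, values, unit, out_of_grammar))
        if scenario in ("SAMPLE_TITLES", "mixed"):
            letter = _SINGLE_LETTER[unit]
            titles = [
                f"cond {letter}{_fmt(v)} rep{r}" for v in values for r in (1, 2)
            ]
        if not titles:
            titles = [f"treated replicate_{r}" for r in range(1, 2 * truth_count + 1)]
        if scenario == "EXPLICIT":
            design_parts.append("Biological duplicates were collected throughout.")

    truth_values = [TimeValue(v, unit) for v in values]

    if rng.random() < spec.confounder_rates.get("patient-age-in-title", 0.0):
        ages = rng.sample(range(38, 78), 3)
        titles = titles + [f"patient {a}y biopsy" for a in ages]
        confounders.append("patient-age-in-title")
    if stratum != "1" and rng.random() < spec.confounder_rates.get(
            "latency-duration-in-text", 0.0):
        lat = sorted(rng.sample(range(3, 30), 3))
        summary_parts.append(
            f"Response latencies of {lat[0]} min, {lat[1]} min and"
            f" {lat[2]} min were recorded for the treated animals."
        )
        confounders.append("latency-duration-in-text")
    if rng.random() < spec.confounder_rates.get("sample-count-echo", 0.0):
        summary_parts.append(f"A total of {len(titles)} samples were analyzed.")
        confounders.append("sample-count-echo")

    meta = SeriesMetadata(
        accession=accession,
        title=title,
        summary=" ".join(summary_parts),
        overall_design=" ".join(design_parts),
        series_type="Expression profiling by array",
        organism=organism,
        sample_titles=titles,
    )
    return SyntheticSeries(meta, truth_count, truth_values, confounders,
                           scenario, out_of_grammar)


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    names = sorted(weights)
    r = rng.random()
    acc = 0.0
    for name in names:
        acc += weights[name]
        if r < acc:
            return name
    return names[-1]


def _stratum_counts(spec: CorpusSpec) -> dict[str, int]:
    """Largest-remainder rounding of strata_weights × n_series."""
    raw = {s: spec.strata_weights.get(s, 0.0) * spec.n_series
           for s in ("1", "2-7", ">7")}
    counts = {s: int(v) for s, v in raw.items()}
    short = spec.n_series - sum(counts.values())
    for s, _ in sorted(raw.items(), key=lambda kv: kv[1] - int(kv[1]), reverse=True):
        if short <= 0:
            break
        counts[s] += 1
        short -= 1
    return counts


def generate_corpus(spec: Optional[CorpusSpec] = None) -> list[SyntheticSeries]:
    """Draw the full corpus; the same spec yields a byte-identical corpus."""
    spec = spec or CorpusSpec()
    rng = random.Random(spec.seed)
    counts = _stratum_counts(spec)
    corpus: list[SyntheticSeries] = []
    i = 0
    for stratum in ("1", "2-7", ">7"):
        for _ in range(counts[stratum]):
            i += 1
            corpus.append(generate_series(spec, stratum, rng, f"GSE9{i:05d}"))
    return corpus


# --- Serialisation -----------------------------------------------------------


def render_soft(meta: SeriesMetadata) -> str:
    """Render one series as SOFT-like plain text (round-trips via the parser)."""
    lines = [f"^SERIES = {meta.accession}"]
    for key, value in (
        ("title", meta.title),
        ("summary", meta.summary),
        ("overall_design", meta.overall_design),
        ("type", meta.series_type),
        ("organism", meta.organism),
    ):
        if value:
            lines.append(f"!Series_{key} = {value}")
    for j, title in enumerate(meta.sample_titles, start=1):
        lines.append(f"^SAMPLE = GSM{j:06d}")
        lines.append(f"!Sample_title = {title}")
    return "\n".join(lines) + "\n"


def write_corpus(corpus: list[SyntheticSeries], out_dir: str | Path) -> Path:
    """Write SOFT-like fixture files plus a ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_path = out_dir / "truth.csv"
    with open(truth_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession", "truth_count", "truth_values", "confounders"])
        for series in corpus:
            (out_dir / f"{series.meta.accession}.soft.txt").write_text(
                render_soft(series.meta), encoding="utf-8"
            )
            writer.writerow([
                series.meta.accession,
                series.truth_count,
                ";".join(format_time_value(v) for v in series.truth_values),
                "|".join(series.confounders),
            ])
    return truth_path
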