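"""Scoring of predicted time-point counts against curated ground truth.

A predicted count is scored both exactly and under the within-±1
criterion: baseline time points are reported inconsistently across
submitters (t=0 may or may not be counted), so even two human curators
commonly disagree by one, and a prediction off by at most one is treated
as correct.  Error rates are additionally stratified by the true count
(1; 2–7 inclusive; over 7, i.e. ≥8), since extraction is markedly easier
for single-time-point series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = ["EvaluationReport", "StratumReport", "score", "stratum_of"]

logger = logging.getLogger(__name__)

STRATA = ("1", "2-7", ">7")


def stratum_of(truth_count: int) -> str:
    if truth_count <= 1:
        return "1"
    if truth_count <= 7:
        return "2-7"
    return ">7"


@dataclass
class StratumReport:
    n: int = 0
    errors_within_one: int = 0

    @property
    def error_rate(self) -> float:
        return self.errors_within_one / self.n if self.n else 0.0


@dataclass
class EvaluationReport:
    """Exact and within-±1 accuracy, with per-stratum error rates."""

    n: int
    exact_correct: int
    within_one_correct: int
    strata: dict[str, StratumReport] = field(default_factory=dict)
    n_excluded: int = 0

    @property
    def exact_accuracy(self) -> float:
        return self.exact_correct / self.n if self.n else 0.0

    @property
    def within_one_accuracy(self) -> float:
        return self.within_one_correct / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "exact_correct": self.exact_correct,
            "within_one_correct": self.within_one_correct,
            "exact_accuracy": self.exact_accuracy,
            "within_one_accuracy": self.within_one_accuracy,
            "n_excluded": self.n_excluded,
            "strata": {
                name: {
                    "n": s.n,
                    "errors_within_one": s.errors_within_one,
                    "error_rate": s.error_rate,
                }
                for name, s in self.strata.items()
            },
        }

    def summary(self) -> str:
        lines = [
            f"n = {self.n} series scored"
            + (f" ({self.n_excluded} super-series excluded)" if self.n_excluded else ""),
            f"exact accuracy:      {self.exact_correct}/{self.n}"
            f" = {100 * self.exact_accuracy:.1f}%",
            f"within-±1 accuracy:  {self.within_one_correct}/{self.n}"
            f" = {100 * self.within_one_accuracy:.1f}%",
        ]
        for name in STRATA:
            s = self.strata.get(name)
            if s is None:
                continue
            lines.append(
                f"  stratum {name:>3}: n={s.n:<4d} errors(±1)={s.errors_within_one:<3d}"
                f" error rate {100 * s.error_rate:.2f}%"
            )
        return "\n".join(lines)


def score(
    truth: Mapping[str, int],
    predicted: Mapping[str, int],
    excluded: Optional[Iterable[str]] = None,
) -> EvaluationReport:
    """Score predictions against truth, keyed by series accession.

    Accessions listed in ``excluded`` (super-series, which never enter
    time-point detection) are dropped from both sides with a logged count.
    The remaining key sets must match exactly; a mismatch raises
    ``ValueError`` naming the differing accessions.
    """
    excluded_set = set(excluded or ())
    truth = {k: v for k, v in truth.items() if k not in excluded_set}
    n_excluded = len(predicted) - len([k for k in predicted if k not in excluded_set])
    predicted = {k: v for k, v in predicted.items() if k not in excluded_set}
    if n_excluded:
        logger.info("dropped %d excluded (super-series) predictions", n_excluded)

    missing = sorted(set(truth) - set(predicted))
    extra = sorted(set(predicted) - set(truth))
    if missing or extra:
        raise ValueError(
            f"truth/prediction key mismatch: missing={missing} extra={extra}"
        )

    report = EvaluationReport(
        n=len(truth), exact_correct=0, within_one_correct=0,
        strata={name: StratumReport() for name in STRATA},
        n_excluded=n_excluded,
    )
    for accession in truth:
        t, p = int(truth[accession]), int(predicted[accession])
        diff = abs(p - t)
        if diff == 0:
            report.exact_correct += 1
        if diff <= 1:
            report.within_one_correct += 1
        stratum = report.strata[stratum_of(t)]
        stratum.n += 1
        if diff > 1:
            stratum.errors_within_one += 1
    return report
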