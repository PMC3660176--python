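"""False-positive / false-negative evaluation of CQ classification.

Given truth labels (autosome / X / Y) the evaluation counts how many
non-Y fragments fall below the CQ threshold and how many true Y fragments
do.  The false-positive rate is the share of below-threshold fragments
that are actually autosomal or X-linked — a false-discovery proportion
with the below-threshold set as denominator, which is the definition that
reproduces the published benchmark rates from their underlying counts
(135/(135+5408) = 2.44%, not 135/621581).  The false-negative rate is the
share of true Y fragments missed by the threshold; capture rate is its
complement.

By default only the CQ threshold is applied, matching how the benchmark
rates were computed; the male/female count gates can optionally be
applied as well (the threshold sweep uses this).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from cqkit.scoring import CQRecord

TRUTH_LABELS = ("autosome", "X", "Y")


class EvaluationError(ValueError):
    """Raised when truth labels are missing or invalid."""


@dataclass(frozen=True)
class EvaluationReport:
    """Counts and derived rates for one classification configuration."""

    n_non_y: int          # autosome + X fragments evaluated
    n_non_y_below: int    # of those, how many fall below the CQ threshold
    n_y: int              # true Y fragments evaluated
    n_y_below: int        # of those, how many fall below the CQ threshold

    @property
    def false_positive_rate(self) -> float:
        """Percent of below-threshold fragments that are non-Y (0 if none below)."""
        below = self.n_non_y_below + self.n_y_below
        return 100.0 * self.n_non_y_below / below if below else 0.0

    @property
    def false_negative_rate(self) -> float:
        """Percent of true Y fragments not captured by the threshold."""
        return 100.0 * (1.0 - self.n_y_below / self.n_y) if self.n_y else 0.0

    @property
    def capture_rate(self) -> float:
        return 100.0 - self.false_negative_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "n_non_y": self.n_non_y,
                "n_non_y_below": self.n_non_y_below,
                "false_positive_rate": round(self.false_positive_rate, 2),
                "n_y": self.n_y,
                "n_y_below": self.n_y_below,
                "false_negative_rate": round(self.false_negative_rate, 2),
                "capture_rate": round(self.capture_rate, 2),
            }]
        )


def evaluate(
    records: Iterable[CQRecord],
    truth: Mapping[str, str],
    cq_max: float = 0.3,
    male_min: int | None = None,
    female_max: int | None = None,
) -> EvaluationReport:
    """Score classified records against truth labels.

    ``truth`` maps fragment_id -> autosome / X / Y.  A fragment counts as
    "below" when its normalized CQ is defined and < cq_max, and — when the
    optional count gates are given — its male count exceeds ``male_min``
    and its female count is under ``female_max``.
    """
    records = list(records)
    if not records:
        raise EvaluationError("no records to evaluate")
    missing = [r.fragment_id for r in records if r.fragment_id not in truth]
    if missing:
        raise EvaluationError(
            f"{len(missing)} records lack truth labels, e.g. {missing[:5]}"
        )
    bad = {truth[r.fragment_id] for r in records} - set(TRUTH_LABELS)
    if bad:
        raise EvaluationError(
            f"truth labels must be in {TRUTH_LABELS}; found {sorted(bad)}"
        )

    n_non_y = n_non_y_below = n_y = n_y_below = 0
    for r in records:
        below = (
            r.normalized_cq is not None
            and r.normalized_cq < cq_max
            and (male_min is None or r.male_count > male_min)
            and (female_max is None or r.female_count < female_max)
        )
        if truth[r.fragment_id] == "Y":
            n_y += 1
            n_y_below += below
        else:
            n_non_y += 1
            n_non_y_below += below
    if n_y == 0 or n_non_y == 0:
        raise EvaluationError(
            "evaluation needs at least one Y and one non-Y fragment "
            f"(got {n_y} Y, {n_non_y} non-Y)"
        )
    return EvaluationReport(n_non_y, n_non_y_below, n_y, n_y_below)
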