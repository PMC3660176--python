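"""Chromosome-quotient computation, normalization and classification.

For fragment S_i with female count F_i and male count M_i the raw CQ is
F_i / M_i (undefined when M_i = 0).  To correct for unequal male/female
sequencing depth, raw CQs are divided by the median raw CQ of fragments
known to be autosomal, so the autosomal median becomes exactly 1.  A
fragment is then called a Y candidate when its normalized CQ is below 0.3
(equivalently, more than 3.33x as many male as female alignments), with
more than 30 male alignments (enough male evidence) and fewer than 30
female alignments (rejecting repeats with extra Y copies).  All three
thresholds are parameters; the defaults are the published ones and the
count comparisons are strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from cqkit.exact_match import CountTable, ReadSet, build_index, count_alignments
from cqkit.fragmenter import Fragment

Y_CANDIDATE = "Y_candidate"
NOT_Y = "not_Y"
UNCLASSIFIABLE = "unclassifiable"


class NormalizationError(ValueError):
    """Raised when the autosomal median CQ cannot be computed."""


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (strict comparisons).

    Y candidate: normalized CQ < cq_max AND male_count > male_min AND
    female_count < female_max.
    """

    cq_max: float = 0.3
    male_min: int = 30
    female_max: int = 30

    def __post_init__(self) -> None:
        if self.cq_max <= 0:
            raise ValueError(f"cq_max must be > 0, got {self.cq_max}")
        if self.male_min < 0:
            raise ValueError(f"male_min must be >= 0, got {self.male_min}")
        if self.female_max < 1:
            raise ValueError(f"female_max must be >= 1, got {self.female_max}")


@dataclass(frozen=True)
class CQRecord:
    """Counts, raw and normalized CQ, and classification for one fragment.

    ``raw_cq`` and ``normalized_cq`` are None when the male count is zero
    (the ratio is undefined; such fragments are never classifiable).
    """

    fragment_id: str
    female_count: int
    male_count: int
    raw_cq: float | None = None
    normalized_cq: float | None = None
    label: str | None = None


@dataclass(frozen=True)
class NormalizationContext:
    """The autosomal-median normalization applied to a batch of records."""

    autosomal_ids: frozenset[str]
    median_autosomal_raw_cq: float
    applied: bool

    @property
    def factor(self) -> float:
        return self.median_autosomal_raw_cq if self.applied else 1.0


def compute_raw_cq(female_count: int, male_count: int) -> float | None:
    """Raw chromosome quotient F/M; None when the male count is zero."""
    if female_count < 0 or male_count < 0:
        raise ValueError(
            f"alignment counts must be non-negative, got "
            f"F={female_count}, M={male_count}"
        )
    if male_count == 0:
        return None
    return female_count / male_count


def report_cq(cq: float | None, decimals: int = 3) -> float | None:
    """Round a CQ for reporting, half away from zero (0.0565 -> 0.057)."""
    if cq is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(cq)).quantize(q, rounding=ROUND_HALF_UP))


def records_from_counts(counts: CountTable) -> list[CQRecord]:
    """Build raw-CQ records (unnormalized, unclassified) from a count table."""
    return [
        CQRecord(
            row.fragment_id,
            int(row.female_count),
            int(row.male_count),
            raw_cq=compute_raw_cq(int(row.female_count), int(row.male_count)),
        )
        for row in counts.table.itertuples()
    ]


def normalize(
    records: Iterable[CQRecord], autosomal_ids: Iterable[str]
) -> tuple[NormalizationContext, list[CQRecord]]:
    """Divide every defined raw CQ by the median autosomal raw CQ.

    The median is taken over the known-autosomal fragments with a defined
    raw CQ (male count > 0); for an even-sized set it is the mean of the
    two central values.  After normalization the autosomal median equals
    exactly 1.  Undefined CQs stay undefined.
    """
    records = list(records)
    auto_ids = frozenset(autosomal_ids)
    auto_cqs = [
        r.raw_cq for r in records if r.fragment_id in auto_ids and r.raw_cq is not None
    ]
    if not auto_cqs:
        raise NormalizationError(
            "no known-autosomal fragment has a defined raw CQ (male count > 0); "
            "rerun without normalization or supply autosomal fragment ids"
        )
    factor = _median(auto_cqs)
    if factor <= 0:
        raise NormalizationError(
            f"median autosomal raw CQ is {factor}; normalization requires a "
            "positive median — rerun without normalization"
        )
    ctx = NormalizationContext(auto_ids, factor, applied=True)
    out = [
        replace(r, normalized_cq=None if r.raw_cq is None else r.raw_cq / factor)
        for r in records
    ]
    return ctx, out


def skip_normalization(records: Iterable[CQRecord]) -> tuple[NormalizationContext, list[CQRecord]]:
    """Pass raw CQs through unchanged (normalized_cq = raw_cq)."""
    out = [replace(r, normalized_cq=r.raw_cq) for r in records]
    return NormalizationContext(frozenset(), 1.0, applied=False), out


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2


def classify(record: CQRecord, th: Thresholds = Thresholds()) -> str:
    """Label one record as Y_candidate / not_Y / unclassifiable.

    Unclassifiable means there is not enough male evidence to call either
    way: male_count <= male_min, which subsumes the undefined-CQ case.
    """
    if record.normalized_cq is None or record.male_count <= th.male_min:
        return UNCLASSIFIABLE
    if record.normalized_cq < th.cq_max and record.female_count < th.female_max:
        return Y_CANDIDATE
    return NOT_Y


def classify_all(
    records: Iterable[CQRecord], th: Thresholds = Thresholds()
) -> list[CQRecord]:
    return [replace(r, label=classify(r, th)) for r in records]


def sweep_male_threshold(
    records: Sequence[CQRecord],
    th_base: Thresholds,
    male_min_values: Sequence[int],
    truth: Mapping[str, str],
) -> pd.DataFrame:
    """Re-evaluate classification across a range of male-alignment gates.

    For each candidate male_min, fragments are reclassified with the base
    thresholds and that gate, and false-positive / false-negative rates
    are computed against the truth labels.  Returns one row per gate:
    (male_min, false_positive_rate, false_negative_rate, n_classifiable).
    """
    from cqkit.evaluation import evaluate  # deferred: avoids import cycle

    if len(male_min_values) == 0:
        raise ValueError("male_min_values must be non-empty")
    rows = []
    for male_min in male_min_values:
        th = replace(th_base, male_min=int(male_min))
        report = evaluate(
            records, truth, cq_max=th.cq_max,
            male_min=th.male_min, female_max=th.female_max,
        )
        n_classifiable = sum(
            1 for r in records
            if r.normalized_cq is not None and r.male_count > th.male_min
        )
        rows.append(
            (th.male_min, report.false_positive_rate, report.false_negative_rate,
             n_classifiable)
        )
    return pd.DataFrame(
        rows,
        columns=["male_min", "false_positive_rate", "false_negative_rate",
                 "n_classifiable"],
    )


def compare_distributions(
    cq_group_a: Sequence[float], cq_group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided, midrank ties) between two CQ groups.

    Returns (U statistic of the first group, two-sided p-value).
    """
    if len(cq_group_a) == 0 or len(cq_group_b) == 0:
        raise ValueError("both CQ groups must be non-empty")
    res = stats.mannwhitneyu(cq_group_a, cq_group_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def screen_expression(
    y_fragments: Sequence[Fragment], rnaseq: ReadSet, min_reads: int = 1
) -> list[tuple[str, int]]:
    """Nominate expressed Y-gene candidates from transcriptome reads.

    A transcriptome read supports a fragment when it matches the fragment
    exactly over its entire length on either strand — stricter than a
    100%-identity local alignment hit, which may cover only part of the
    read.  Fragments with at least ``min_reads`` supporting reads are
    returned sorted by support (descending; ties by fragment id).
    """
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    if not y_fragments or not rnaseq.reads:
        return []
    usable = [r for r in rnaseq.reads if "N" not in r]
    if not usable:
        return []
    k = min(len(r) for r in usable)
    index = build_index(y_fragments, k=k)
    counts = count_alignments(index, rnaseq, mode="presence")
    hits = [
        (fid, n) for fid, n in counts.counts.items() if n >= min_reads
    ]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def records_to_frame(records: Iterable[CQRecord]) -> pd.DataFrame:
    """Tabulate records with 3-decimal reported CQs alongside full precision."""
    rows = [
        {
            "fragment_id": r.fragment_id,
            "female_count": r.female_count,
            "male_count": r.male_count,
            "raw_cq": r.raw_cq,
            "normalized_cq": r.normalized_cq,
            "reported_cq": report_cq(r.normalized_cq),
            "label": r.label,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["fragment_id", "female_count", "male_count", "raw_cq",
                 "normalized_cq", "reported_cq", "label"],
    )
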