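"""End-to-end glue: fragment -> count -> score -> classify (-> evaluate)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from cqkit.evaluation import EvaluationReport, evaluate
from cqkit.exact_match import (
    CountTable,
    ReadSet,
    build_index,
    count_alignments,
)
from cqkit.fragmenter import (
    DEFAULT_MIN_LENGTH,
    Fragment,
    MaskedSequence,
    fragment_masked,
)
from cqkit.scoring import (
    CQRecord,
    NormalizationContext,
    Thresholds,
    classify_all,
    normalize,
    records_from_counts,
    records_to_frame,
    skip_normalization,
)
from cqkit.sexsim import (
    AUTOSOME,
    SimTruth,
    SimulationConfig,
    simulate_genome,
    simulate_reads,
)


def fragment_genome(
    genome: Sequence[MaskedSequence], min_length: int = DEFAULT_MIN_LENGTH
) -> list[Fragment]:
    """Fragment every sequence of a genome, preserving source order."""
    frags: list[Fragment] = []
    for seq in genome:
        frags.extend(fragment_masked(seq, min_length))
    return frags


def count_read_sets(
    frags: Sequence[Fragment],
    female: ReadSet,
    male: ReadSet,
    k: int | None = None,
    mode: str = "presence",
) -> CountTable:
    """Count exact full-length matches of both read sets per fragment.

    k defaults to the shortest N-free read across both sets, so every
    usable read can be queried.
    """
    if k is None:
        lengths = [
            len(r) for rs in (female, male) for r in rs.reads if "N" not in r
        ]
        if not lengths:
            raise ValueError("no N-free reads in either read set; cannot pick k")
        k = min(lengths)
    index = build_index(frags, k=k)
    female_counts = count_alignments(index, female, mode=mode)
    male_counts = count_alignments(index, male, mode=mode)
    return CountTable.from_counts(frags, female_counts, male_counts)


@dataclass
class SimulationRun:
    """Everything produced by a simulate-and-score run."""

    config: SimulationConfig
    genome: list[MaskedSequence]
    truth: SimTruth
    fragments: list[Fragment]
    counts: CountTable
    context: NormalizationContext
    records: list[CQRecord]
    truth_labels: dict[str, str]      # fragment_id -> autosome/X/Y

    @property
    def frame(self) -> pd.DataFrame:
        df = records_to_frame(self.records)
        df["truth_label"] = df["fragment_id"].map(self.truth_labels)
        return df

    def cqs_by_compartment(self) -> dict[str, list[float]]:
        """Defined normalized CQs grouped by truth compartment."""
        out: dict[str, list[float]] = {}
        for rec in self.records:
            if rec.normalized_cq is not None:
                out.setdefault(self.truth_labels[rec.fragment_id], []).append(
                    rec.normalized_cq
                )
        return out

    def evaluate(
        self,
        cq_max: float | None = None,
        male_min: int | None = None,
        female_max: int | None = None,
    ) -> EvaluationReport:
        return evaluate(
            self.records,
            self.truth_labels,
            cq_max=0.3 if cq_max is None else cq_max,
            male_min=male_min,
            female_max=female_max,
        )


def run_simulation_pipeline(
    cfg: SimulationConfig,
    thresholds: Thresholds = Thresholds(),
    min_length: int = DEFAULT_MIN_LENGTH,
    mode: str = "presence",
    apply_normalization: bool = True,
) -> SimulationRun:
    """Simulate a genome and reads, then run the full CQ pipeline.

    Normalization uses the true autosomal fragment ids from the simulator
    (the 'known autosomal sequences' a real analysis would supply).
    """
    genome, truth = simulate_genome(cfg)
    male, female, _ = simulate_reads(genome, truth, cfg)
    frags = fragment_genome(genome, min_length=min_length)
    if not frags:
        raise ValueError(
            "simulation produced no fragments of the required length; "
            "lower min_length or reduce repeat density"
        )
    counts = count_read_sets(frags, female, male, mode=mode)
    records = records_from_counts(counts)
    truth_labels = truth.fragment_compartments(frags)
    if apply_normalization:
        autosomal_ids = {
            fid for fid, comp in truth_labels.items() if comp == AUTOSOME
        }
        context, records = normalize(records, autosomal_ids)
    else:
        context, records = skip_normalization(records)
    records = classify_all(records, thresholds)
    return SimulationRun(
        cfg, genome, truth, frags, counts, context, records, truth_labels
    )
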