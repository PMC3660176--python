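"""Sex-chromosome genome and read simulator with ground-truth labels.

The simulator emulates the genomic features that make Y-sequence
discovery hard, without requiring any external data:

* an XY/XX ploidy model — per-individual chromosome copy numbers of
  autosome 2 / X 1 / Y 1 in males and autosome 2 / X 2 / Y 0 in females,
  which set the expected read-depth ratios behind CQ ~ 1 (autosome),
  ~ 2 (X) and 0 (Y-unique);
* interspersed repeat families with diverged copies shared between the
  Y and the autosomes/X (the Y at higher multiplicity), softmasked in
  the emitted FASTA exactly as RepeatMasker would mark them;
* recent duplications from autosome/X donors onto the Y at configurable
  nucleotide identity (default 95%), which exact matching must reject;
* error-free or low-error fixed-length reads at configurable
  per-individual haploid coverage, drawn uniformly from either strand;
* planted "expressed" Y-gene intervals from which transcriptome reads
  are drawn.

Everything is reproducible from the config seed, and a SimTruth object
records per-sequence compartments, planted intervals and per-fragment
labels for downstream evaluation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from cqkit.exact_match import ReadSet, reverse_complement
from cqkit.fragmenter import Fragment, MaskedSequence
from cqkit.tsvio import write_tsv

_BASES = np.frombuffer(b"ACGT", dtype="S1")

AUTOSOME, X, Y = "autosome", "X", "Y"

# per-copy depth multipliers under the XY/XX ploidy model
PLOIDY = {
    "male": {AUTOSOME: 2, X: 1, Y: 1},
    "female": {AUTOSOME: 2, X: 2, Y: 0},
}


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulator; the seed fixes every random choice.

    Coverage is per-individual haploid depth: a compartment present in c
    copies is sequenced at ``coverage * c``.  Lengths are in bases.
    """

    seed: int = 0
    n_autosomal_seqs: int = 5
    autosomal_length: int = 50_000
    x_length: int = 50_000
    y_length: int = 20_000
    repeat_family_count: int = 2
    repeat_unit_length: int = 150
    repeat_copies_per_compartment: int = 30
    repeat_copies_y: int = 24
    repeat_divergence_percent: float = 2.0
    n_duplications: int = 2
    duplication_length: int = 500
    duplication_identity_percent: float = 95.0
    read_length: int = 100
    male_coverage: float = 20.0
    female_coverage: float = 20.0
    sequencing_error_rate: float = 0.0
    n_expressed_y_genes: int = 2
    expressed_gene_length: int = 500
    transcript_reads_per_gene: int = 50

    def __post_init__(self) -> None:
        for name in ("autosomal_length", "x_length", "y_length"):
            if getattr(self, name) < self.read_length:
                raise SimulationError(
                    f"{name}={getattr(self, name)} is shorter than "
                    f"read_length={self.read_length}"
                )
        if self.n_duplications and not (50 < self.duplication_identity_percent <= 100):
            raise SimulationError(
                "duplication_identity_percent must be in (50, 100], got "
                f"{self.duplication_identity_percent}"
            )
        if self.male_coverage <= 0 or self.female_coverage <= 0:
            raise SimulationError("coverage must be > 0")
        if not 0 <= self.sequencing_error_rate < 1:
            raise SimulationError("sequencing_error_rate must be in [0, 1)")
        if self.n_expressed_y_genes and self.expressed_gene_length < self.read_length:
            raise SimulationError(
                "expressed_gene_length must be >= read_length so transcript "
                "reads fit inside the gene"
            )

    def to_json(self, dest: Union[str, Path]) -> None:
        with open(dest, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated genome.

    ``compartment_of`` maps sequence id to autosome/X/Y; interval lists
    are 0-based half-open against the named sequence.
    """

    compartment_of: dict[str, str]
    repeat_intervals: dict[str, list[tuple[int, int]]]
    duplications: list[dict]          # y_start, y_end, donor_id, donor_start, donor_end
    expressed_genes: list[tuple[int, int]]   # intervals on the Y sequence
    y_id: str = "Y"

    def fragment_compartments(self, frags: Iterable[Fragment]) -> dict[str, str]:
        """Truth label per fragment, inherited from the source sequence."""
        out = {}
        for frag in frags:
            try:
                out[frag.fragment_id] = self.compartment_of[frag.source_id]
            except KeyError:
                raise KeyError(
                    f"fragment {frag.fragment_id} references unknown source "
                    f"{frag.source_id!r}"
                ) from None
        return out

    def fragment_flags(self, frags: Iterable[Fragment]) -> dict[str, str]:
        """unique / repeat / duplication flag per fragment (by overlap)."""
        out = {}
        for frag in frags:
            flag = "unique"
            for s, e in self.repeat_intervals.get(frag.source_id, ()):
                if s < frag.end and frag.start < e:
                    flag = "repeat"
                    break
            if flag == "unique" and frag.source_id == self.y_id:
                for dup in self.duplications:
                    if dup["y_start"] < frag.end and frag.start < dup["y_end"]:
                        flag = "duplication"
                        break
            out[frag.fragment_id] = flag
        return out

    def fragment_table(self, frags: Sequence[Fragment]) -> pd.DataFrame:
        comp = self.fragment_compartments(frags)
        flags = self.fragment_flags(frags)
        return pd.DataFrame(
            {
                "fragment_id": [f.fragment_id for f in frags],
                "truth_label": [comp[f.fragment_id] for f in frags],
                "flag": [flags[f.fragment_id] for f in frags],
            }
        )

    def to_tsv(self, frags: Sequence[Fragment], dest: Union[str, Path]) -> None:
        write_tsv(self.fragment_table(frags), dest)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently with probability ``rate``.

    Substitutions always change the base (drawn from the other three).
    """
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _place_intervals(
    rng: np.random.Generator,
    seq_len: int,
    sizes: Sequence[int],
    occupied: list[tuple[int, int]],
    what: str,
    max_tries: int = 200,
) -> list[int]:
    """Choose non-overlapping start positions for intervals of given sizes."""
    starts = []
    for size in sizes:
        if size > seq_len:
            raise SimulationError(
                f"cannot place {what}: interval of {size} bases exceeds "
                f"sequence length {seq_len}"
            )
        for _ in range(max_tries):
            s = int(rng.integers(0, seq_len - size + 1))
            if all(not (s < e and o < s + size) for o, e in occupied):
                break
        else:
            raise SimulationError(
                f"cannot place {what}: no free interval of {size} bases found "
                f"after {max_tries} tries (sequence too crowded)"
            )
        occupied.append((s, s + size))
        starts.append(s)
    return starts


def simulate_genome(cfg: SimulationConfig) -> tuple[list[MaskedSequence], SimTruth]:
    """Generate a softmasked reference with known compartments.

    Random ACGT backbones per compartment; diverged repeat-family copies
    are planted and lowercased; duplication donors from autosomes/X are
    mutated to the target identity and written into the Y; expressed-gene
    intervals are reserved on repeat-free, duplication-free Y sequence.
    """
    rng = np.random.default_rng(cfg.seed)

    names = [f"autosome_{i + 1}" for i in range(cfg.n_autosomal_seqs)] + ["X", "Y"]
    lengths = [cfg.autosomal_length] * cfg.n_autosomal_seqs + [cfg.x_length, cfg.y_length]
    compartments = [AUTOSOME] * cfg.n_autosomal_seqs + [X, Y]
    arrays = {name: _random_seq(rng, ln) for name, ln in zip(names, lengths)}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    repeat_intervals: dict[str, list[tuple[int, int]]] = {name: [] for name in names}

    # Large features claim their intervals first, then the numerous short
    # repeats fill in around them; the reverse order would leave no
    # contiguous gap on a repeat-dense Y.

    # recent duplications: autosome/X donor segments copied onto Y, diverged
    duplications: list[dict] = []
    donor_pool = names[:-1]  # all but Y
    dup_rate = 1.0 - cfg.duplication_identity_percent / 100.0
    for _ in range(cfg.n_duplications):
        donor_id = donor_pool[int(rng.integers(0, len(donor_pool)))]
        (donor_start,) = _place_intervals(
            rng, len(arrays[donor_id]), [cfg.duplication_length],
            occupied[donor_id], f"duplication donor on {donor_id}",
        )
        (y_start,) = _place_intervals(
            rng, len(arrays["Y"]), [cfg.duplication_length],
            occupied["Y"], "duplication target on Y",
        )
        donor_seq = arrays[donor_id][donor_start : donor_start + cfg.duplication_length]
        arrays["Y"][y_start : y_start + cfg.duplication_length] = _mutate(
            rng, donor_seq, dup_rate
        )
        duplications.append(
            {
                "y_start": y_start,
                "y_end": y_start + cfg.duplication_length,
                "donor_id": donor_id,
                "donor_start": donor_start,
                "donor_end": donor_start + cfg.duplication_length,
            }
        )

    # expressed Y genes on unique (repeat- and duplication-free) Y sequence
    gene_starts = _place_intervals(
        rng, len(arrays["Y"]),
        [cfg.expressed_gene_length] * cfg.n_expressed_y_genes,
        occupied["Y"], "expressed Y genes",
    )
    expressed = [(s, s + cfg.expressed_gene_length) for s in sorted(gene_starts)]

    # interspersed repeats, shared between compartments, more copies on Y
    div = cfg.repeat_divergence_percent / 100.0
    for _ in range(cfg.repeat_family_count):
        unit = _random_seq(rng, cfg.repeat_unit_length)
        for name, comp in zip(names, compartments):
            n_copies = (
                cfg.repeat_copies_y if comp == Y else cfg.repeat_copies_per_compartment
            )
            if n_copies == 0:
                continue
            starts = _place_intervals(
                rng, len(arrays[name]), [cfg.repeat_unit_length] * n_copies,
                occupied[name], f"repeat copies on {name}",
            )
            for s in starts:
                copy = _mutate(rng, unit, div)
                arrays[name][s : s + cfg.repeat_unit_length] = copy
                repeat_intervals[name].append((s, s + cfg.repeat_unit_length))

    seqs = []
    for name in names:
        residues = arrays[name].tobytes().decode("ascii")
        masked = bytearray(residues, "ascii")
        for s, e in repeat_intervals[name]:
            masked[s:e] = residues[s:e].lower().encode("ascii")
        seqs.append(
            MaskedSequence(name, masked.decode("ascii"), description="simulated")
        )
    truth = SimTruth(
        compartment_of=dict(zip(names, compartments)),
        repeat_intervals={k: sorted(v) for k, v in repeat_intervals.items()},
        duplications=duplications,
        expressed_genes=expressed,
    )
    return seqs, truth


def simulate_reads(
    genome: Sequence[MaskedSequence], truth: SimTruth, cfg: SimulationConfig
) -> tuple[ReadSet, ReadSet, ReadSet]:
    """Draw sex-separated genomic reads and Y-gene transcriptome reads.

    Read counts per sequence follow depth = coverage x copy number under
    the ploidy model; positions are uniform, strands equiprobable, and an
    optional per-base substitution error is applied.  Transcriptome reads
    come only from the planted expressed Y-gene intervals, error-free.
    """
    rng = np.random.default_rng([cfg.seed, 7])
    unmasked = {s.seq_id: s.residues.upper() for s in genome}

    pools = {}
    for sex, coverage in (("male", cfg.male_coverage), ("female", cfg.female_coverage)):
        reads: list[str] = []
        for seq in genome:
            copies = PLOIDY[sex][truth.compartment_of[seq.seq_id]]
            if copies == 0:
                continue
            n_reads = int(round(coverage * copies * len(seq) / cfg.read_length))
            if n_reads == 0:
                continue
            reads.extend(
                _draw_reads(
                    rng, unmasked[seq.seq_id], n_reads, cfg.read_length,
                    cfg.sequencing_error_rate,
                )
            )
        pools[sex] = ReadSet(sex, reads, origin=f"simulated:seed={cfg.seed}")

    transcript_reads: list[str] = []
    y_seq = unmasked[truth.y_id]
    for s, e in truth.expressed_genes:
        transcript_reads.extend(
            _draw_reads(
                rng, y_seq[s:e], cfg.transcript_reads_per_gene, cfg.read_length, 0.0
            )
        )
    transcriptome = ReadSet(
        "transcriptome", transcript_reads, origin=f"simulated:seed={cfg.seed}"
    )
    return pools["male"], pools["female"], transcriptome


def _draw_reads(
    rng: np.random.Generator, template: str, n_reads: int, read_length: int,
    error_rate: float,
) -> list[str]:
    positions = rng.integers(0, len(template) - read_length + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5
    reads = []
    for pos, rev in zip(positions, flip):
        read = template[pos : pos + read_length]
        if error_rate > 0:
            arr = _mutate(rng, np.frombuffer(read.encode(), dtype="S1"), error_rate)
            read = arr.tobytes().decode("ascii")
        reads.append(reverse_complement(read) if rev else read)
    return reads


def write_genome_fasta(
    genome: Iterable[MaskedSequence], dest: Union[str, Path], width: int = 70
) -> None:
    """Write the softmasked genome as wrapped FASTA."""
    with open(dest, "w") as fh:
        for seq in genome:
            fh.write(f">{seq.seq_id} {seq.description}".rstrip() + "\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def write_reads_fastq(readset: ReadSet, dest: Union[str, Path]) -> None:
    """Write reads as FASTQ with constant dummy qualities."""
    with open(dest, "w") as fh:
        for i, read in enumerate(readset.reads):
            fh.write(f"@{readset.label}_{i}\n{read}\n+\n{'I' * len(read)}\n")
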