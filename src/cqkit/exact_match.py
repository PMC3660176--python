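"""Exact full-length read matching against reference fragments.

The alignment criterion is deliberately strict: a read counts toward a
fragment only if every base of the read matches the fragment, with zero
mismatches and no clipping, on either strand.  This strictness is what
lets a female-to-male alignment ratio reject reads from a recent (e.g.
95%-identity) autosomal paralog: any read covering a diverged site fails
the exact-match test.

Matching is seed-and-verify: fragments are indexed by their k-mers
(default k = shortest read length) and each candidate position is verified
over the full read length.  In the default per-fragment-presence counting
mode a read adds at most 1 to each fragment it matches anywhere; the
all-occurrences mode counts every distinct match position.  The choice
only matters for fragments with internal repetition.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence, Union

import pandas as pd
import pysam
from Bio import SeqIO

from cqkit.fragmenter import Fragment
from cqkit.tsvio import read_tsv, write_tsv

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PRESENCE = "presence"
ALL_OCCURRENCES = "occurrences"
_MODE_ALIASES = {
    "presence": PRESENCE,
    "per-fragment-presence": PRESENCE,
    "occurrences": ALL_OCCURRENCES,
    "all-occurrences": ALL_OCCURRENCES,
}

_READ_ALPHABET = set("ACGTN")


class ReadSetError(ValueError):
    """Raised for malformed read input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadSet:
    """A labelled collection of reads (sequences only; qualities ignored).

    ``label`` is one of male / female / transcriptome / other; ``origin``
    records the file path or simulator tag the reads came from.
    """

    label: str
    reads: list[str]
    origin: str = ""

    VALID_LABELS = ("male", "female", "transcriptome", "other")

    def __post_init__(self) -> None:
        if self.label not in self.VALID_LABELS:
            raise ReadSetError(
                f"read-set label must be one of {self.VALID_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.reads)

    @classmethod
    def from_file(
        cls, path: Union[str, Path], label: str, fmt: str | None = None
    ) -> "ReadSet":
        """Load reads from FASTA or FASTQ, optionally gzip-compressed.

        The format is sniffed from the first character when not given.
        """
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            if fmt is None:
                first = fh.read(1)
                fh.seek(0)
                if first == ">":
                    fmt = "fasta"
                elif first == "@":
                    fmt = "fastq"
                else:
                    raise ReadSetError(
                        f"{path}: cannot determine read format (starts with {first!r})"
                    )
            reads = [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]
        return cls(label, reads, origin=str(path))


@dataclass
class AlignmentCounts:
    """Per-fragment exact-match counts for one read set."""

    counts: dict[str, int]
    n_reads: int
    n_counted: int
    n_skipped: int
    mode: str
    label: str


class ExactMatchIndex:
    """Seed-and-verify substring index over a fragment collection.

    Every k-mer of every fragment (forward strand) is recorded with its
    position; a query of length >= k is located by looking up its leading
    k-mer and verifying the full query, and strand symmetry is obtained by
    also querying the reverse complement.  Deterministic for fixed inputs.
    """

    def __init__(self, fragments: Sequence[Fragment], k: int):
        if k < 1:
            raise ValueError(f"k must be a positive integer, got {k}")
        self.k = k
        self.fragments = list(fragments)
        self._kmers: dict[str, list[tuple[int, int]]] = {}
        for idx, frag in enumerate(self.fragments):
            seq = frag.residues
            for pos in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[pos : pos + k], []).append((idx, pos))

    def locate(self, query: str) -> dict[int, set[int]]:
        """All exact occurrences of ``query`` (either strand) per fragment.

        Returns {fragment index: set of 0-based match positions}.  Forward
        and reverse-complement matches at the same position (palindromic
        queries) collapse to one occurrence.
        """
        if len(query) < self.k:
            raise ValueError(
                f"query length {len(query)} < index k = {self.k}"
            )
        hits: dict[int, set[int]] = {}
        for q in {query, reverse_complement(query)}:
            for idx, pos in self._kmers.get(q[: self.k], ()):
                frag_seq = self.fragments[idx].residues
                if frag_seq[pos : pos + len(q)] == q:
                    hits.setdefault(idx, set()).add(pos)
        return hits


def build_index(frags: Sequence[Fragment], k: int) -> ExactMatchIndex:
    """Build an exact-match index supporting queries of length >= k."""
    return ExactMatchIndex(frags, k)


def count_alignments(
    index: ExactMatchIndex, readset: ReadSet, mode: str = PRESENCE
) -> AlignmentCounts:
    """Count zero-mismatch full-length read matches per fragment.

    Reads containing N, or shorter than the index k, cannot match exactly
    and are skipped (tallied).  In presence mode each read adds at most 1
    per fragment it matches; in all-occurrences mode each distinct match
    position adds 1.
    """
    try:
        mode = _MODE_ALIASES[mode]
    except KeyError:
        raise ValueError(f"unknown counting mode {mode!r}") from None
    counts = {frag.fragment_id: 0 for frag in index.fragments}
    ids = [frag.fragment_id for frag in index.fragments]
    n_counted = n_skipped = 0
    for i, read in enumerate(readset.reads):
        if not set(read) <= _READ_ALPHABET:
            bad = next(ch for ch in read if ch not in _READ_ALPHABET)
            raise ReadSetError(
                f"read {i} of {readset.label} set contains invalid base {bad!r}"
            )
        if "N" in read or len(read) < index.k:
            n_skipped += 1
            continue
        hits = index.locate(read)
        if hits:
            n_counted += 1
            for idx, positions in hits.items():
                counts[ids[idx]] += 1 if mode == PRESENCE else len(positions)
    if n_skipped:
        logger.warning(
            "%s read set: skipped %d of %d reads (contain N or shorter than k=%d)",
            readset.label, n_skipped, len(readset.reads), index.k,
        )
    return AlignmentCounts(
        counts, len(readset.reads), n_counted, n_skipped, mode, readset.label
    )


@dataclass
class CountTable:
    """Female and male exact-match counts per fragment (F_i and M_i).

    Every fragment of the reference appears exactly once; metadata records
    the totals per read set.
    """

    table: pd.DataFrame  # fragment_id, female_count, male_count, length
    metadata: dict = field(default_factory=dict)

    REQUIRED = ("fragment_id", "female_count", "male_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if self.table["fragment_id"].duplicated().any():
            dup = self.table.loc[self.table["fragment_id"].duplicated(), "fragment_id"]
            raise ValueError(f"duplicate fragment ids in count table: {list(dup[:5])}")
        if (self.table[["female_count", "male_count"]] < 0).any().any():
            raise ValueError("alignment counts must be non-negative")

    @classmethod
    def from_counts(
        cls,
        frags: Sequence[Fragment],
        female: AlignmentCounts,
        male: AlignmentCounts,
    ) -> "CountTable":
        rows = [
            (f.fragment_id, female.counts[f.fragment_id], male.counts[f.fragment_id], len(f))
            for f in frags
        ]
        df = pd.DataFrame(rows, columns=["fragment_id", "female_count", "male_count", "length"])
        meta = {
            "female_reads_total": female.n_reads,
            "female_reads_counted": female.n_counted,
            "female_reads_skipped": female.n_skipped,
            "male_reads_total": male.n_reads,
            "male_reads_counted": male.n_counted,
            "male_reads_skipped": male.n_skipped,
            "mode": male.mode,
        }
        return cls(df, meta)

    def to_tsv(self, dest: Union[str, Path]) -> None:
        write_tsv(self.table, dest)

    @classmethod
    def from_tsv(cls, source: Union[str, Path]) -> "CountTable":
        return cls(read_tsv(source))


def ingest_sam(
    alignments: Union[str, Path, IO[str]],
    frags: Sequence[Fragment],
    mode: str = PRESENCE,
    label: str = "other",
) -> AlignmentCounts:
    """Build per-fragment counts from externally produced SAM records.

    Only records that are mapped, unclipped over the full read length and
    mismatch-free count: the NM tag must be 0 when present, otherwise the
    CIGAR must be pure match (M/=) with an MD tag, if any, consistent with
    zero mismatches.  Records naming unknown fragments are skipped with a
    warning; in presence mode duplicate (read, fragment) pairs collapse.
    """
    try:
        mode = _MODE_ALIASES[mode]
    except KeyError:
        raise ValueError(f"unknown counting mode {mode!r}") from None
    known = {frag.fragment_id for frag in frags}
    counts = {frag.fragment_id: 0 for frag in frags}
    seen_pairs: set[tuple[str, str]] = set()
    n_records = n_counted = n_skipped = 0
    unknown_refs: set[str] = set()

    path = str(alignments) if isinstance(alignments, (str, Path)) else alignments
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            n_records += 1
            if rec.is_unmapped or rec.reference_name is None:
                n_skipped += 1
                continue
            if rec.reference_name not in known:
                unknown_refs.add(rec.reference_name)
                n_skipped += 1
                continue
            if not _is_full_length_exact(rec):
                n_skipped += 1
                continue
            key = (rec.query_name or "", rec.reference_name)
            if mode == PRESENCE:
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
            counts[rec.reference_name] += 1
            n_counted += 1
    if unknown_refs:
        logger.warning(
            "SAM ingestion: skipped records referencing %d unknown fragments (e.g. %s)",
            len(unknown_refs), sorted(unknown_refs)[:3],
        )
    return AlignmentCounts(counts, n_records, n_counted, n_skipped, mode, label)


def _is_full_length_exact(rec: "pysam.AlignedSegment") -> bool:
    cigar = rec.cigartuples
    if not cigar:
        return False
    # op codes: 0=M, 7=[=], 8=X; anything else (clips, indels, skips) fails
    if any(op not in (0, 7) for op, _ in cigar):
        return False
    if rec.has_tag("NM"):
        return rec.get_tag("NM") == 0
    if rec.has_tag("MD"):
        md = str(rec.get_tag("MD"))
        return md.isdigit() and int(md) == rec.query_length
    return True
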