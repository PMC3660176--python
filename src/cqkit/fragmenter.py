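"""Fragment softmasked references into repeat-free, gap-free pieces.

Softmasked assemblies mark repeats in lowercase (RepeatMasker convention)
and assembly gaps with N.  Because repeats are shared between the Y and
the autosomes/X, they confound a female-to-male alignment ratio; they are
therefore removed, splitting each reference sequence into the maximal runs
of uppercase, non-N residues.  Fragments below a minimum length (default
250 bp) are dropped to mitigate false positives from spurious exact
matches.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio import SeqIO

DEFAULT_MIN_LENGTH = 250

_MASKED_ALPHABET = set("ACGTNacgtn")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVryswkmbdhv")
# maximal runs of unmasked, unambiguous residues
_FRAGMENT_RE = re.compile(r"[ACGT]+")


class FragmenterError(ValueError):
    """Raised for invalid masked-sequence input."""


@dataclass(frozen=True)
class MaskedSequence:
    """A named reference sequence with lowercase repeat masking.

    Lowercase residues mark repeats; N (either case) marks gaps or
    ambiguity.  Any other residue is rejected unless ``permissive``
    parsing mapped it to N first.
    """

    seq_id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FragmenterError(f"sequence {self.seq_id!r} is empty")
        bad = _first_invalid(self.residues)
        if bad is not None:
            raise FragmenterError(
                f"sequence {self.seq_id!r}: invalid residue "
                f"{self.residues[bad]!r} at offset {bad}; expected A/C/G/T/N "
                "in either case (use permissive parsing to map IUPAC "
                "ambiguity codes to N)"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _first_invalid(residues: str) -> int | None:
    for i, ch in enumerate(residues):
        if ch not in _MASKED_ALPHABET:
            return i
    return None


@dataclass(frozen=True)
class Fragment:
    """A repeat-free, gap-free slice of a reference sequence.

    ``fragment_id`` encodes provenance as ``source_id:start-end`` with
    0-based half-open coordinates against the original (masked) sequence.
    """

    source_id: str
    start: int
    end: int
    residues: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FragmenterError(
                f"fragment on {self.source_id!r}: bad interval "
                f"[{self.start}, {self.end})"
            )
        if len(self.residues) != self.end - self.start:
            raise FragmenterError(
                f"fragment on {self.source_id!r}: residues length "
                f"{len(self.residues)} != end - start = {self.end - self.start}"
            )
        if not set(self.residues) <= set("ACGT"):
            raise FragmenterError(
                f"fragment on {self.source_id!r}: residues must be uppercase ACGT"
            )

    @property
    def fragment_id(self) -> str:
        return f"{self.source_id}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return len(self.residues)


def fragment_masked(
    seq: MaskedSequence, min_length: int = DEFAULT_MIN_LENGTH
) -> list[Fragment]:
    """Split a masked sequence at every masked or ambiguous base.

    Returns the maximal runs of uppercase A/C/G/T, in source order, keeping
    only runs of at least ``min_length`` bases.  Both lowercase (repeat)
    runs and N/n runs act as separators; isolated masked bases split too.
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    return [
        Fragment(seq.seq_id, m.start(), m.end(), m.group())
        for m in _FRAGMENT_RE.finditer(seq.residues)
        if m.end() - m.start() >= min_length
    ]


def read_masked_fasta(
    source: Union[str, Path, IO[str]], permissive: bool = False
) -> Iterator[MaskedSequence]:
    """Parse a (multi-record, wrapped or unwrapped) softmasked FASTA.

    With ``permissive=True``, IUPAC ambiguity codes (R, Y, S, ...) are
    mapped to N (case-preserved) instead of raising.
    """
    seen: set[str] = set()
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in seen:
            raise FragmenterError(f"duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if permissive:
            residues = "".join(
                ("N" if ch.isupper() else "n") if ch in _IUPAC_AMBIGUOUS else ch
                for ch in residues
            )
        yield MaskedSequence(rec.id, residues, rec.description)


def write_fragments(frags: Iterable[Fragment], dest: Union[str, Path, IO[str]]) -> None:
    """Write fragments as FASTA with ``fragment_id`` headers (unwrapped)."""
    if hasattr(dest, "write"):
        _write_fragment_fasta(frags, dest)  # type: ignore[arg-type]
    else:
        with open(dest, "w") as fh:
            _write_fragment_fasta(frags, fh)


def _write_fragment_fasta(frags: Iterable[Fragment], fh: IO[str]) -> None:
    for frag in frags:
        fh.write(f">{frag.fragment_id}\n{frag.residues}\n")


def read_fragments(source: Union[str, Path, IO[str]]) -> list[Fragment]:
    """Read fragments back from FASTA written by :func:`write_fragments`."""
    frags = []
    for rec in SeqIO.parse(source, "fasta"):
        source_id, _, span = rec.id.rpartition(":")
        try:
            start_s, end_s = span.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FragmenterError(
                f"header {rec.id!r} is not of the form source:start-end"
            ) from exc
        frags.append(Fragment(source_id, start, end, str(rec.seq)))
    return frags
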