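"""Nucleotide sequence primitives shared by all modules.

Conventions used throughout the package:

* coordinates are 0-based, half-open ``[start, end)``;
* sequences are uppercase-normalized on construction and must be
  unambiguous (``ACGT`` for DNA, ``ACGU`` for RNA) — IUPAC ambiguity codes
  are allowed only in motif *patterns*;
* hits on the minus strand are reported in plus-strand coordinates: the
  interval whose reverse complement matches the motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal

from .errors import AlphabetError, KindError, PatternError

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: IUPAC nucleotide codes -> the set of unambiguous DNA bases they stand for.
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Complement of each IUPAC code (complement of the base *set*).
IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

Strand = Literal["plus", "minus"]
StrandChoice = Literal["plus", "minus", "both"]


def _validate(residues: str, kind: str) -> str:
    """Uppercase-fold and alphabet-check a raw residue string."""
    folded = residues.upper()
    alphabet = DNA_ALPHABET if kind == "dna" else RNA_ALPHABET
    for i, ch in enumerate(folded):
        if ch not in alphabet:
            raise AlphabetError(
                f"invalid {kind.upper()} character {ch!r} at position {i}"
            )
    return folded


@dataclass(frozen=True)
class NucSeq:
    """An unambiguous nucleotide sequence.

    Parameters
    ----------
    residues:
        The sequence string; lowercase is folded to uppercase.
    kind:
        ``"dna"`` (alphabet ACGT) or ``"rna"`` (alphabet ACGU).
    """

    residues: str
    kind: Literal["dna", "rna"] = "dna"

    def __post_init__(self) -> None:
        if self.kind not in ("dna", "rna"):
            raise KindError(f"unknown sequence kind {self.kind!r}")
        object.__setattr__(self, "residues", _validate(self.residues, self.kind))

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class MotifPattern:
    """A fixed-length IUPAC motif (e.g. ``NGG``, ``TTTV``, ``GCTCTTC``)."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        for i, ch in enumerate(pat):
            if ch not in IUPAC_DNA:
                raise PatternError(
                    f"invalid IUPAC code {ch!r} at position {i} in motif {pat!r}"
                )
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(self.pattern.translate(IUPAC_COMPLEMENT)[::-1])

    def to_regex(self) -> re.Pattern[str]:
        parts = []
        for ch in self.pattern:
            bases = sorted(IUPAC_DNA[ch])
            parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
        return re.compile("".join(parts))


@dataclass(frozen=True)
class StrandHit:
    """A motif occurrence, always in plus-strand coordinates.

    ``strand == "minus"`` means the reverse complement of
    ``sequence[start:end]`` matches the motif.
    """

    start: int
    end: int
    strand: Strand

    def sort_key(self) -> tuple[int, int]:
        # plus before minus at equal start
        return (self.start, 0 if self.strand == "plus" else 1)


def reverse_complement(seq: NucSeq | str, kind: str = "dna") -> NucSeq:
    """Reverse complement of a DNA or RNA sequence.

    Accepts a plain string (interpreted with ``kind``) or a :class:`NucSeq`;
    returns a :class:`NucSeq` of the same kind. ``reverse_complement`` is an
    involution and preserves length and GC count.
    """
    if not isinstance(seq, NucSeq):
        seq = NucSeq(seq, kind)  # type: ignore[arg-type]
    table = _DNA_COMPLEMENT if seq.kind == "dna" else _RNA_COMPLEMENT
    return NucSeq(seq.residues.translate(table)[::-1], seq.kind)


def revcomp_str(s: str) -> str:
    """Reverse complement of an unambiguous DNA string (string in/out)."""
    return str(reverse_complement(NucSeq(s, "dna")))


def transcribe(seq: NucSeq | str) -> NucSeq:
    """Transcribe the sense/coding DNA strand into RNA (T -> U)."""
    if not isinstance(seq, NucSeq):
        seq = NucSeq(seq, "dna")
    if seq.kind != "dna":
        raise KindError("transcribe expects DNA input")
    return NucSeq(seq.residues.replace("T", "U"), "rna")


def dna_from_rna(seq: NucSeq | str) -> NucSeq:
    """Explicit RNA -> DNA conversion (U -> T); never performed silently."""
    if not isinstance(seq, NucSeq):
        seq = NucSeq(seq, "rna")
    if seq.kind != "rna":
        raise KindError("dna_from_rna expects RNA input")
    return NucSeq(seq.residues.replace("U", "T"), "dna")


def find_sites(
    seq: NucSeq | str,
    motif: MotifPattern | str,
    strands: StrandChoice = "both",
) -> list[StrandHit]:
    """All occurrences of an IUPAC motif on the requested strand(s).

    Overlapping hits are all reported. A palindromic motif matching both
    strands over the same interval is reported once, as a plus-strand hit
    (one physical site). A motif longer than the sequence yields an empty
    list. Results are sorted by start, plus before minus at equal start.
    """
    if not isinstance(seq, NucSeq):
        seq = NucSeq(seq, "dna")
    if not isinstance(motif, MotifPattern):
        motif = MotifPattern(motif)
    if strands not in ("plus", "minus", "both"):
        raise ValueError(f"unknown strand choice {strands!r}")

    s = seq.residues
    k = len(motif)
    if k == 0 or k > len(s):
        return []

    hits: list[StrandHit] = []
    plus_intervals: set[tuple[int, int]] = set()
    if strands in ("plus", "both"):
        rx = re.compile("(?=(" + motif.to_regex().pattern + "))")
        for m in rx.finditer(s):
            start = m.start()
            hits.append(StrandHit(start, start + k, "plus"))
            plus_intervals.add((start, start + k))
    if strands in ("minus", "both"):
        # a minus hit at [i, i+k) <=> plus strand matches RC(motif) there
        rc_rx = re.compile("(?=(" + motif.reverse_complement().to_regex().pattern + "))")
        for m in rc_rx.finditer(s):
            start = m.start()
            if strands == "both" and (start, start + k) in plus_intervals:
                continue  # palindromic site: one physical site, report once
            hits.append(StrandHit(start, start + k, "minus"))
    hits.sort(key=StrandHit.sort_key)
    return hits


def gc_count(seq: NucSeq | str) -> int:
    s = seq.residues if isinstance(seq, NucSeq) else seq.upper()
    return s.count("G") + s.count("C")


def iter_kmers(s: str, k: int) -> Iterable[tuple[int, str]]:
    for i in range(len(s) - k + 1):
        yield i, s[i : i + k]
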