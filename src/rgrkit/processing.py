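"""Transcript assembly and ribozyme self-cleavage simulation.

Models the Pol II transcript carrying an optional upstream ORF (e.g. an
mCherry-like reporter), a multiplex RGR array and an optional trailer,
then predicts every fragment released by hammerhead/HDV self-cleavage.
Cleavage chemistry is reduced to exact junction cuts: the hammerhead cuts
at its own 3' boundary (so the released guide's 5' end is exact and the
HH byproduct keeps the stem), the HDV at its own 5' boundary (guide 3'
end exact). Partial processing is modeled combinatorially via per-site
flags; no kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .design import MultiplexArray
from .errors import DesignError
from .seqcore import NucSeq, transcribe

Role = Literal["upstream_byproduct", "guide", "inter_byproduct",
               "downstream_byproduct"]


@dataclass(frozen=True)
class CleavageSite:
    """One ribozyme cut position on the transcript (0-based RNA index)."""

    position: int
    kind: Literal["hh", "hdv"]
    cassette_label: str


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its ribozyme cleavage sites located."""

    upstream_orf: str
    array: MultiplexArray
    trailer: str
    rna: str
    sites: tuple[CleavageSite, ...]

    @property
    def cleavage_positions(self) -> list[int]:
        return [s.position for s in self.sites]


@dataclass(frozen=True)
class CleavageProduct:
    """An RNA fragment released by (possibly partial) self-cleavage."""

    sequence: str
    role: Role
    source_label: str = "-"


def assemble_transcript(array: MultiplexArray,
                        upstream_orf: str | None = None,
                        trailer: str | None = None) -> TranscriptModel:
    """Build the transcript model for an array (plus optional ORF/trailer).

    The RNA is the transcription of ``upstream_orf + array + trailer``;
    each cassette contributes one HH site (hh/guide-body boundary) and one
    HDV site (guide-body/hdv boundary), so an n-cassette array yields 2n
    strictly increasing sites.
    """
    if not array.cassettes:
        raise DesignError("transcript needs a non-empty array")
    orf = str(NucSeq(upstream_orf)) if upstream_orf else ""
    trail = str(NucSeq(trailer)) if trailer else ""

    dna = orf + array.full_sequence + trail
    rna = str(transcribe(dna))

    sites: list[CleavageSite] = []
    for offset, cassette in zip(array.cassette_offsets(), array.cassettes):
        hh_end, gb_end, _ = cassette.boundaries
        base = len(orf) + offset
        sites.append(CleavageSite(base + hh_end, "hh", cassette.label))
        sites.append(CleavageSite(base + gb_end, "hdv", cassette.label))
    return TranscriptModel(upstream_orf=orf, array=array, trailer=trail,
                           rna=rna, sites=tuple(sites))


def simulate_cleavage(t: TranscriptModel,
                      efficiency: Literal["complete"] | Sequence[bool] = "complete",
                      ) -> list[CleavageProduct]:
    """Cut the transcript at its ribozyme sites and label every fragment.

    ``efficiency="complete"`` cuts at every site (2n cuts -> 2n+1
    fragments); a boolean flag sequence (one per site, transcript order)
    cuts only the flagged sites, modeling partial processing. Fragments
    concatenate back to the transcript exactly. A fragment whose ends are
    exactly one cassette's HH and HDV sites is a released guide; the
    fragment before the first cut / after the last cut are the upstream /
    downstream byproducts; anything else between cuts is an
    inter-cassette byproduct.
    """
    if efficiency == "complete":
        flags = [True] * len(t.sites)
    else:
        flags = list(efficiency)
        if len(flags) != len(t.sites):
            raise DesignError(
                f"need {len(t.sites)} per-site flags, got {len(flags)}"
            )
    cut_sites = [s for s, f in zip(t.sites, flags) if f]
    positions = [s.position for s in cut_sites]

    # guide intervals: (hh cut, hdv cut) per cassette, by label
    guide_intervals: dict[tuple[int, int], str] = {}
    by_label: dict[str, dict[str, int]] = {}
    for s in t.sites:
        by_label.setdefault(s.cassette_label, {})[s.kind] = s.position
    for label, d in by_label.items():
        guide_intervals[(d["hh"], d["hdv"])] = label

    bounds = [0] + positions + [len(t.rna)]
    products: list[CleavageProduct] = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        frag = t.rna[a:b]
        if (a, b) in guide_intervals:
            products.append(CleavageProduct(frag, "guide", guide_intervals[(a, b)]))
        elif i == 0:
            products.append(CleavageProduct(frag, "upstream_byproduct"))
        elif i == len(bounds) - 2:
            products.append(CleavageProduct(frag, "downstream_byproduct"))
        else:
            products.append(CleavageProduct(frag, "inter_byproduct"))
    return products


def released_guides(products: Sequence[CleavageProduct]) -> list[tuple[str, str]]:
    """The guide-role fragments, in transcript order, as (label, RNA)."""
    return [(p.source_label, p.sequence) for p in products if p.role == "guide"]


def products_to_fasta(products: Sequence[CleavageProduct]) -> str:
    """FASTA export of cleavage products (role and label in description)."""
    lines = []
    for i, p in enumerate(products):
        lines.append(f">fragment_{i:02d} role={p.role} label={p.source_label}")
        lines.append(p.sequence)
    return "\n".join(lines) + ("\n" if lines else "")
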