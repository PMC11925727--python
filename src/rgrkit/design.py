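"""RGR cassette and multiplex-array design.

The ribozyme–gRNA–ribozyme (RGR) cassette places a guide between two
self-cleaving ribozymes so that a plain RNA polymerase II transcript can
release a functional guide with exact 5' and 3' ends:

    hammerhead (HH) — guide body — hepatitis delta virus (HDV)

The one guide-specific design step is the HH closing stem: the first six
nucleotides of the hammerhead are the reverse complement of the six
nucleotides immediately following the hammerhead's 3' end, so that helix I
forms against the nascent guide. For SpCas9 the guide body is
spacer + sgRNA scaffold, so the stem pairs with the spacer; for LbCas12a
the crRNA leads with the constant direct repeat, so the stem pairs with
the repeat and is the same for every Cas12a guide. Cassettes are
concatenated into multiplex arrays and flanked with type IIS arms for
directional Golden Gate insertion into a destination vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import CloningError, DesignError
from .registry import PartRegistry, TypeIISEnzyme
from .seqcore import NucSeq, StrandHit, find_sites, revcomp_str

logger = logging.getLogger("rgrkit")

CasSystem = Literal["spcas9", "lbcas12a"]

#: Default spacer lengths per Cas system (nt). Configurable per Spacer.
DEFAULT_SPACER_LEN: dict[str, int] = {"spcas9": 20, "lbcas12a": 23}

#: Accepted spacer length bounds (nt).
SPACER_LEN_BOUNDS = (18, 25)

#: PAM geometry per Cas system: (IUPAC pattern, side relative to the
#: protospacer). SpCas9 reads an NGG immediately 3' of the protospacer;
#: LbCas12a a TTTV immediately 5' of it. The PAM is never part of the spacer.
PAM_GEOMETRY: dict[str, tuple[str, str]] = {
    "spcas9": ("NGG", "three_prime"),
    "lbcas12a": ("TTTV", "five_prime"),
}


@dataclass(frozen=True)
class Spacer:
    """A guide's target-matching segment plus its Cas-system assignment."""

    sequence: str
    cas: CasSystem
    label: str

    def __post_init__(self) -> None:
        if self.cas not in ("spcas9", "lbcas12a"):
            raise DesignError(f"spacer {self.label!r}: unknown Cas system {self.cas!r}")
        seq = str(NucSeq(self.sequence))  # alphabet check + fold
        object.__setattr__(self, "sequence", seq)
        lo, hi = SPACER_LEN_BOUNDS
        if not lo <= len(seq) <= hi:
            raise DesignError(
                f"spacer {self.label!r}: length {len(seq)} outside [{lo}, {hi}]"
            )


def design_stem(downstream_six: str) -> str:
    """Stem for a hammerhead ribozyme: reverse complement of the six
    nucleotides immediately following the ribozyme's 3' end."""
    seq = str(NucSeq(downstream_six))
    if len(seq) != 6:
        raise DesignError(f"stem source must be exactly 6 nt, got {len(seq)}")
    return revcomp_str(seq)


@dataclass(frozen=True)
class RGRCassette:
    """A concrete HH–guide body–HDV cassette.

    ``full_sequence`` is the DNA-level concatenation ``hh + guide_body +
    hdv``; boundary coordinates (0-based, half-open) are recorded so
    downstream modules can place cleavage sites exactly.
    """

    spacer: Spacer
    stem: str
    hh: str
    guide_body: str
    hdv: str
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stem != revcomp_str(self.guide_body[:6]):
            raise DesignError(
                f"cassette {self.spacer.label!r}: stem is not the reverse "
                "complement of the first six nt of the guide body"
            )
        if not self.hh.startswith(self.stem):
            raise DesignError(
                f"cassette {self.spacer.label!r}: hammerhead does not start "
                "with the designed stem"
            )

    @property
    def full_sequence(self) -> str:
        return self.hh + self.guide_body + self.hdv

    @property
    def boundaries(self) -> tuple[int, int, int]:
        """(hh end, guide_body end, total length) within the cassette."""
        a = len(self.hh)
        b = a + len(self.guide_body)
        return a, b, b + len(self.hdv)

    @property
    def label(self) -> str:
        return self.spacer.label


def build_rgr(spacer: Spacer, registry: PartRegistry,
              hh_name: str | None = None, hdv_name: str | None = None,
              scaffold_name: str | None = None) -> RGRCassette:
    """Build one RGR cassette for a spacer.

    The guide body is ``spacer + scaffold`` for SpCas9 and
    ``direct repeat + spacer`` for LbCas12a; the stem is computed from the
    first six nt of whichever sequence follows the hammerhead. Internal
    type IIS recognition sites (any registered enzyme) are recorded as
    warnings — they only become fatal when cloning arms are added.
    """
    hh_template = registry.get_part("hh_template", hh_name)
    hdv = registry.get_part("hdv", hdv_name)
    if spacer.cas == "spcas9":
        scaffold = registry.get_part("cas9_scaffold", scaffold_name)
        guide_body = spacer.sequence + scaffold.sequence
    else:
        repeat = registry.get_part("cas12a_direct_repeat", scaffold_name)
        guide_body = repeat.sequence + spacer.sequence

    stem = design_stem(guide_body[:6])
    hh = stem + hh_template.body

    cassette_seq = hh + guide_body + hdv.sequence
    warnings = tuple(
        f"{enz.name} site at [{hit.start}, {hit.end}) ({hit.strand} strand)"
        for enz, hit in _enzyme_hits(cassette_seq, registry.enzymes.values())
    )
    for w in warnings:
        logger.warning("cassette %s: internal %s", spacer.label, w)

    return RGRCassette(spacer=spacer, stem=stem, hh=hh,
                       guide_body=guide_body, hdv=hdv.sequence,
                       warnings=warnings)


def _enzyme_hits(seq: str, enzymes) -> list[tuple[TypeIISEnzyme, StrandHit]]:
    out = []
    for enz in enzymes:
        for hit in find_sites(NucSeq(seq), enz.recognition, "both"):
            out.append((enz, hit))
    return out


@dataclass(frozen=True)
class MultiplexArray:
    """Ordered RGR cassettes on one transcript, with an optional linker."""

    cassettes: tuple[RGRCassette, ...]
    linker: str = ""

    @property
    def full_sequence(self) -> str:
        return self.linker.join(c.full_sequence for c in self.cassettes)

    def cassette_offsets(self) -> list[int]:
        """Start offset of each cassette within ``full_sequence``."""
        offsets, pos = [], 0
        for c in self.cassettes:
            offsets.append(pos)
            pos += len(c.full_sequence) + len(self.linker)
        return offsets


def build_array(spacers: Sequence[Spacer], registry: PartRegistry,
                linker: str = "") -> MultiplexArray:
    """Build a multiplex array: one cassette per spacer, input order kept."""
    if not spacers:
        raise DesignError("cannot build an array from zero spacers")
    labels = [s.label for s in spacers]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise DesignError(f"duplicate spacer labels: {dupes}")
    linker = str(NucSeq(linker)) if linker else ""
    cassettes = tuple(build_rgr(s, registry) for s in spacers)
    return MultiplexArray(cassettes=cassettes, linker=linker)


@dataclass(frozen=True)
class ClonedFragment:
    """An array flanked by inward-pointing type IIS arms, ready to digest.

    Digesting ``sequence`` with ``enzyme`` removes both recognition sites
    and releases the array as an insert carrying the configured 5'
    overhangs (stored as plus-strand images).
    """

    array: MultiplexArray
    enzyme: TypeIISEnzyme
    arm5: str
    arm3: str
    overhang5: str
    overhang3: str

    @property
    def sequence(self) -> str:
        return self.arm5 + self.array.full_sequence + self.arm3

    def to_ds(self):
        """Blunt linear duplex view (see :mod:`rgrkit.cloning`)."""
        from .cloning import DsFragment
        return DsFragment(self.sequence)


def add_cloning_arms(array: MultiplexArray, enzyme: TypeIISEnzyme,
                     overhang_pair: tuple[str, str],
                     spacer_nt: str | None = None) -> ClonedFragment:
    """Flank an array with type IIS recognition arms for Golden Gate.

    Arms are oriented so both recognition sites point inward: digestion
    removes them from the insert and leaves the designed 5' overhangs
    (o5 on the left, o3 on the right, both given as plus-strand images).
    ``spacer_nt`` is the filler between the recognition site and the cut
    window; its length must equal the enzyme's top-strand cut offset.
    """
    o5, o3 = (str(NucSeq(o)) for o in overhang_pair)
    ovh = enzyme.overhang_len
    if len(o5) != ovh or len(o3) != ovh:
        raise DesignError(
            f"overhang length mismatch: {enzyme.name} leaves {ovh}-nt "
            f"overhangs, got {len(o5)} and {len(o3)}"
        )
    if o5 == o3:
        raise DesignError("identical overhangs o5 == o3 break directionality")
    if o5 == revcomp_str(o3):
        raise DesignError(
            "o5 is the reverse complement of o3: the insert could ligate "
            "in the flipped orientation"
        )
    if o5 == revcomp_str(o5) or o3 == revcomp_str(o3):
        raise DesignError("self-complementary overhangs break directionality")

    filler = str(NucSeq(spacer_nt)) if spacer_nt is not None else "A" * enzyme.cut_offset_top
    if len(filler) != enzyme.cut_offset_top:
        raise DesignError(
            f"spacer_nt must be exactly {enzyme.cut_offset_top} nt for "
            f"{enzyme.name} (cut offset), got {len(filler)}"
        )

    internal = find_sites(NucSeq(array.full_sequence), enzyme.recognition, "both")
    if internal:
        positions = ", ".join(
            f"[{h.start}, {h.end}) {h.strand}" for h in internal
        )
        raise CloningError(
            f"array contains internal {enzyme.name} recognition site(s) at "
            f"{positions}; the fragment would shatter on digestion"
        )

    rec = enzyme.recognition.pattern  # unambiguous for real type IIS enzymes
    arm5 = rec + filler + o5
    arm3 = o3 + filler + revcomp_str(rec)
    return ClonedFragment(array=array, enzyme=enzyme, arm5=arm5, arm3=arm3,
                          overhang5=o5, overhang3=o3)


def domesticate_check(seq: str | NucSeq,
                      enzymes: Sequence[TypeIISEnzyme]) -> list[tuple[str, StrandHit]]:
    """Scan a sequence for internal type IIS recognition sites.

    Returns every hit on either strand as ``(enzyme name, hit)``; an empty
    list means the sequence is domesticated for all given enzymes.
    """
    if not isinstance(seq, NucSeq):
        seq = NucSeq(seq)
    out: list[tuple[str, StrandHit]] = []
    for enz in enzymes:
        for hit in find_sites(seq, enz.recognition, "both"):
            out.append((enz.name, hit))
    out.sort(key=lambda t: (t[1].start, t[0]))
    return out


@dataclass(frozen=True)
class TargetWindow:
    """Promoter window for CRISPRa guides, in bp upstream of the TSS.

    Positions between ``min_upstream`` and ``max_upstream`` bases upstream
    of the TSS (both bounds inclusive) are eligible; the entire
    protospacer must fit inside the window.
    """

    min_upstream: int = 75
    max_upstream: int = 300

    def __post_init__(self) -> None:
        if not 0 < self.min_upstream < self.max_upstream:
            raise DesignError(
                f"invalid window: need 0 < min ({self.min_upstream}) < "
                f"max ({self.max_upstream})"
            )


@dataclass(frozen=True)
class CandidateSpacer:
    """A protospacer candidate found in a promoter scan.

    Coordinates are plus-strand, 0-based half-open over the protospacer
    only (the PAM is adjacent, never included). ``spacer`` is in
    guide-sense orientation. ``dist_to_tss`` measures from the
    TSS-proximal protospacer base to the TSS.
    """

    spacer: Spacer
    start: int
    end: int
    strand: str
    pam: str
    dist_to_tss: int


def find_candidate_spacers(promoter: NucSeq | str, tss: int, cas: CasSystem,
                           window: TargetWindow | None = None,
                           spacer_len: int | None = None,
                           label_prefix: str = "cand") -> list[CandidateSpacer]:
    """Enumerate CRISPRa protospacer candidates upstream of a TSS.

    Both strands are scanned. A candidate needs a correctly placed PAM
    (NGG 3'-adjacent for SpCas9, TTTV 5'-adjacent for LbCas12a, read on
    the guide strand) and a protospacer lying entirely within the closed
    window ``[tss - max_upstream, tss - min_upstream]`` in plus-strand
    coordinates. Sorted by plus-strand start, plus before minus.
    """
    if not isinstance(promoter, NucSeq):
        promoter = NucSeq(promoter)
    if window is None:
        window = TargetWindow()
    if spacer_len is None:
        spacer_len = DEFAULT_SPACER_LEN[cas]
    s = promoter.residues
    if not 0 <= tss <= len(s):
        raise DesignError(f"tss {tss} outside sequence of length {len(s)}")

    win_lo = tss - window.max_upstream          # leftmost eligible position
    win_hi = tss - window.min_upstream          # rightmost eligible position
    if win_hi < 0 or win_lo + spacer_len - 1 > win_hi:
        logger.warning(
            "window [%d, %d] upstream of tss=%d leaves no room for a %d-nt "
            "protospacer", window.max_upstream, window.min_upstream, tss,
            spacer_len,
        )
        return []

    pam_pattern, pam_side = PAM_GEOMETRY[cas]
    pam_len = len(pam_pattern)

    from .seqcore import IUPAC_DNA

    def matches(sub: str, pattern: str) -> bool:
        return len(sub) == len(pattern) and all(
            ch in IUPAC_DNA[p] for ch, p in zip(sub, pattern)
        )

    out: list[CandidateSpacer] = []
    lo = max(win_lo, 0)
    hi = min(win_hi, len(s) - 1)
    idx = 0
    for start in range(lo, hi - spacer_len + 2):
        end = start + spacer_len
        if end - 1 > hi or end > len(s):
            break
        proto = s[start:end]
        for strand in ("plus", "minus"):
            if strand == "plus":
                if pam_side == "three_prime":
                    pam = s[end : end + pam_len]
                else:
                    pam = s[start - pam_len : start] if start >= pam_len else ""
                guide = proto
            else:
                # PAM positions mirror on the minus strand; read guide-sense
                if pam_side == "three_prime":
                    pam_plus = s[start - pam_len : start] if start >= pam_len else ""
                else:
                    pam_plus = s[end : end + pam_len]
                pam = revcomp_str(pam_plus) if pam_plus else ""
                guide = revcomp_str(proto)
            if not matches(pam, pam_pattern):
                continue
            sp = Spacer(sequence=guide, cas=cas,
                        label=f"{label_prefix}_{cas}_{idx:03d}")
            idx += 1
            out.append(CandidateSpacer(
                spacer=sp, start=start, end=end, strand=strand, pam=pam,
                dist_to_tss=tss - (end - 1),
            ))
    out.sort(key=lambda c: (c.start, 0 if c.strand == "plus" else 1))
    return out
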