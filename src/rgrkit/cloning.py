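"""In-silico type IIS digestion and Golden Gate ligation.

Double-stranded fragments are the currency here. A linear
:class:`DsFragment` is stored as the *plus-strand image* of its full span
(the union of both strands' extents) plus the lengths of its 5'
single-stranded extensions:

* at a **left** end a 5' overhang is a protrusion of the **top** strand,
  so the overhang reads directly off the span prefix;
* at a **right** end a 5' overhang is a protrusion of the **bottom**
  strand, stored via its plus-strand image (the span suffix); the actual
  5'->3' bottom-strand sequence is its reverse complement.

Two ends ligate when their plus-strand images are identical and non-empty
(Watson–Crick complementary single strands annealing); blunt ends are
never joined. Only 5'-overhang enzymes (SapI/LguI, BbsI, ...) are
supported — the registry rejects 3'-overhang geometries at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import CloningError, ExplosionGuardError
from .registry import TypeIISEnzyme
from .seqcore import NucSeq, find_sites, revcomp_str

logger = logging.getLogger("rgrkit")

#: Junction-graph exploration cap for :func:`ligate`.
DEFAULT_STATE_CAP = 10_000


@dataclass(frozen=True)
class DsFragment:
    """Double-stranded DNA with explicit 5' overhangs.

    ``span`` is the plus-strand image of the whole extent. For a linear
    fragment, the top strand is ``span[:len(span) - right_ovh]`` and the
    bottom strand is the reverse complement of ``span[left_ovh:]``.
    Circular fragments have no overhangs and ``span`` is one chosen
    rotation of the plus strand.
    """

    span: str
    left_ovh: int = 0
    right_ovh: int = 0
    topology: Literal["linear", "circular"] = "linear"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "span", str(NucSeq(self.span)))
        if self.topology == "circular":
            if self.left_ovh or self.right_ovh:
                raise CloningError("circular fragments cannot carry overhangs")
        else:
            if self.left_ovh < 0 or self.right_ovh < 0:
                raise CloningError("negative overhang length")
            if self.left_ovh + self.right_ovh > len(self.span):
                raise CloningError("overhangs longer than the fragment")

    # -- derived views ----------------------------------------------------
    @property
    def top(self) -> str:
        """Top strand, 5'->3' (includes the left overhang)."""
        return self.span[: len(self.span) - self.right_ovh]

    @property
    def bottom(self) -> str:
        """Bottom strand, 5'->3' (includes the right overhang)."""
        return revcomp_str(self.span[self.left_ovh :])

    @property
    def left_overhang(self) -> str:
        """Left 5' overhang as it reads on the top strand."""
        return self.span[: self.left_ovh]

    @property
    def right_overhang(self) -> str:
        """Right 5' overhang as it reads on the bottom strand (5'->3')."""
        return revcomp_str(self.right_overhang_plus)

    @property
    def right_overhang_plus(self) -> str:
        """Plus-strand image of the right 5' overhang."""
        return self.span[len(self.span) - self.right_ovh :]

    def flipped(self) -> "DsFragment":
        """The same molecule viewed from the other strand."""
        if self.topology == "circular":
            return DsFragment(revcomp_str(self.span), topology="circular",
                              name=self.name)
        return DsFragment(revcomp_str(self.span), left_ovh=self.right_ovh,
                          right_ovh=self.left_ovh, name=self.name)

    @property
    def duplex_interior(self) -> str:
        """Plus-strand image of the fully double-stranded region."""
        return self.span[self.left_ovh : len(self.span) - self.right_ovh]


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation among both strands of a circle."""
    best = None
    for s in (seq, revcomp_str(seq)):
        doubled = s + s
        for i in range(len(s)):
            rot = doubled[i : i + len(s)]
            if best is None or rot < best:
                best = rot
    return best or ""


# -- digestion -------------------------------------------------------------

def _cut_events(span: str, enzyme: TypeIISEnzyme, circular: bool) -> list[tuple[int, int]]:
    """(top cut, bottom cut) plus-strand positions for every site.

    For a plus-strand site ending at ``e`` the cuts fall at
    ``(e + top, e + bottom)``; for a minus-strand site starting at ``s``
    they fall at ``(s - bottom, s - top)``. Either way bottom > top, i.e.
    a 5' overhang of ``span[p_top:p_bottom]``.
    """
    rec_len = len(enzyme.recognition)
    if circular:
        # extend the scan window so sites and cuts wrapping the origin are seen
        pad = rec_len + enzyme.cut_offset_bottom
        scan = span + span[: min(pad, len(span))]
    else:
        scan = span
    events: list[tuple[int, int]] = []
    for hit in find_sites(NucSeq(scan), enzyme.recognition, "both"):
        if hit.start >= len(span):
            continue  # duplicate from the circular pad
        if hit.strand == "plus":
            p1 = hit.end + enzyme.cut_offset_top
            p2 = hit.end + enzyme.cut_offset_bottom
        else:
            p1 = hit.start - enzyme.cut_offset_bottom
            p2 = hit.start - enzyme.cut_offset_top
        if circular:
            p1m = p1 % len(span)
            events.append((p1m, p1m + (p2 - p1)))
        else:
            if p1 < 0 or p2 > len(span):
                raise CloningError(
                    f"{enzyme.name} site at [{hit.start}, {hit.end}) "
                    f"({hit.strand} strand) cuts outside the fragment"
                )
            events.append((p1, p2))
    events.sort()
    return events


def digest(frag: DsFragment, enzyme: TypeIISEnzyme) -> list[DsFragment]:
    """Cut a fragment at every recognition site of a type IIS enzyme.

    A linear fragment with k internal cuts yields k+1 fragments; a
    circular one with k cuts yields k linear fragments. Fragments are
    reported 5'->3' in plus-strand order; with no sites the input is
    returned unchanged. Sites whose cut positions fall off a linear end
    raise :class:`CloningError`.
    """
    span = frag.span
    circular = frag.topology == "circular"
    events = _cut_events(span, enzyme, circular)
    if not events:
        return [frag]

    if not circular:
        # parent ends act as pseudo-cuts carrying the existing overhangs
        left_end = (0, frag.left_ovh)
        right_end = (len(span) - frag.right_ovh, len(span))
        cuts = [left_end] + events + [right_end]
        for (a1, a2), (b1, b2) in zip(cuts, cuts[1:]):
            if b1 < a2:
                raise CloningError(
                    f"{enzyme.name} cut windows overlap at positions "
                    f"{a1}..{a2} and {b1}..{b2}"
                )
        out = []
        for i, ((a1, a2), (b1, b2)) in enumerate(zip(cuts, cuts[1:])):
            out.append(DsFragment(span[a1:b2], left_ovh=a2 - a1,
                                  right_ovh=b2 - b1,
                                  name=f"{frag.name}.{i}" if frag.name else ""))
        return out

    # circular: k cuts -> k linear fragments, wrapping the origin
    n = len(span)
    doubled = span + span
    out = []
    for i, (a1, a2) in enumerate(events):
        b1, b2 = events[(i + 1) % len(events)]
        if (i + 1) == len(events):
            b1, b2 = b1 + n, b2 + n
        if b1 < a2:
            raise CloningError(f"{enzyme.name} cut windows overlap on circle")
        out.append(DsFragment(doubled[a1:b2], left_ovh=a2 - a1,
                              right_ovh=b2 - b1,
                              name=f"{frag.name}.{i}" if frag.name else ""))
    return out


# -- ligation --------------------------------------------------------------

@dataclass
class AssemblyResult:
    """Outcome of a ligation / Golden Gate reaction."""

    constructs: list[DsFragment] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)
    leftovers: list[DsFragment] = field(default_factory=list)


def _ends_join(a: DsFragment, b: DsFragment) -> bool:
    """Can b's left end ligate onto a's right end?"""
    return (a.right_ovh > 0 and b.left_ovh > 0
            and a.right_overhang_plus == b.left_overhang)


def ligate(fragments: Sequence[DsFragment],
           state_cap: int = DEFAULT_STATE_CAP) -> AssemblyResult:
    """Exhaustively ligate fragments into every distinct circular closure.

    Each fragment may appear once per construct, in either orientation.
    Two ends join when their 5' overhangs are Watson–Crick complementary
    (identical plus-strand images); blunt ends never ligate. Circles are
    deduplicated by canonical rotation (strand-agnostic), so the result
    is invariant to input permutation. Exploration beyond ``state_cap``
    chain states raises :class:`ExplosionGuardError`.
    """
    if not fragments:
        raise CloningError("ligate needs at least one fragment")
    frags = list(fragments)
    oriented = [(f, f.flipped()) for f in frags]

    constructs: dict[str, DsFragment] = {}
    diagnostics: list[dict] = []
    used_in_construct: set[int] = set()
    states = 0

    def extend(chain: list[tuple[int, bool]]) -> None:
        nonlocal states
        states += 1
        if states > state_cap:
            raise ExplosionGuardError(
                f"ligation junction graph exceeded {state_cap} states"
            )
        head_idx, head_flip = chain[0]
        tail_idx, tail_flip = chain[-1]
        head = oriented[head_idx][1 if head_flip else 0]
        tail = oriented[tail_idx][1 if tail_flip else 0]

        # try to close the circle (need >= 1 fragment; self-circularization
        # of a single fragment is allowed when its own ends match)
        if _ends_join(tail, head):
            seq = "".join(
                oriented[i][1 if fl else 0].top for i, fl in chain
            )
            key = canonical_rotation(seq)
            if key not in constructs:
                constructs[key] = DsFragment(key, topology="circular")
                for (i, fl), (j, fl2) in zip(chain, chain[1:] + chain[:1]):
                    up = oriented[i][1 if fl else 0]
                    diagnostics.append({
                        "construct": key[:12] + "...",
                        "upstream": frags[i].name or f"frag{i}",
                        "downstream": frags[j].name or f"frag{j}",
                        "overhang": up.right_overhang_plus,
                        "upstream_flipped": fl,
                        "downstream_flipped": fl2,
                    })
                used_in_construct.update(i for i, _ in chain)
        # extend with any unused fragment, either orientation; fragments
        # with an index below the chain start are excluded — each circle is
        # still found, rooted at its minimal-index member
        in_chain = {i for i, _ in chain}
        for j in range(chain[0][0] + 1, len(frags)):
            if j in in_chain:
                continue
            for flip in (False, True):
                nxt = oriented[j][1 if flip else 0]
                if _ends_join(tail, nxt):
                    extend(chain + [(j, flip)])

    for i in range(len(frags)):
        # both start orientations; strand-agnostic canonicalization dedupes
        extend([(i, False)])
        extend([(i, True)])

    leftovers = [f for i, f in enumerate(frags) if i not in used_in_construct]
    result = AssemblyResult(
        constructs=sorted(constructs.values(), key=lambda c: c.span),
        diagnostics=diagnostics,
        leftovers=leftovers,
    )
    return result


def golden_gate(vector: DsFragment, inserts: Sequence[DsFragment],
                enzyme: TypeIISEnzyme,
                state_cap: int = DEFAULT_STATE_CAP) -> AssemblyResult:
    """One-pot Golden Gate: digest everything, ligate, keep site-free circles.

    The vector must be circular and carry at least two recognition sites
    (the dropout cassette). All fragments are digested to completion;
    post-digest fragments still containing a recognition site (arms, the
    dropout) can only re-create cuttable junctions, so the cut–ligate
    fixpoint keeps only closures free of the enzyme's sites. Diagnostics
    record every junction of every closure plus a note for each discarded
    site-carrying fragment.
    """
    if vector.topology != "circular":
        raise CloningError("destination vector must be circular")
    n_sites = len(find_sites(NucSeq(vector.span + vector.span[:len(enzyme.recognition) - 1]),
                             enzyme.recognition, "both"))
    if n_sites < 2:
        raise CloningError(
            f"vector carries {n_sites} {enzyme.name} site(s); a dropout "
            "cassette needs at least two"
        )

    pool: list[DsFragment] = []
    for frag in [vector, *inserts]:
        pool.extend(digest(frag, enzyme))

    discarded_notes = []
    keep: list[DsFragment] = []
    for f in pool:
        if find_sites(NucSeq(f.span), enzyme.recognition, "both"):
            discarded_notes.append({
                "discarded_fragment": f.name or f.span[:16] + "...",
                "reason": f"still carries a {enzyme.name} recognition site",
            })
        else:
            keep.append(f)

    if not keep:
        return AssemblyResult(constructs=[], diagnostics=discarded_notes,
                              leftovers=pool)

    result = ligate(keep, state_cap=state_cap)
    # defensive: canonical closures must be site-free (guaranteed by the
    # fragment filter, since every closure is a concatenation of kept spans)
    result.constructs = [
        c for c in result.constructs
        if not find_sites(
            NucSeq(c.span + c.span[: len(enzyme.recognition) - 1]),
            enzyme.recognition, "both")
    ]
    result.diagnostics.extend(discarded_notes)
    if not result.constructs:
        result.diagnostics.append({
            "reason": "no site-free circular closure; check overhang "
                      "orientation and complementarity",
        })
    return result


def junction_table(result: AssemblyResult) -> str:
    """Tab-delimited junction report with a header line."""
    cols = ["construct", "upstream", "downstream", "overhang",
            "upstream_flipped", "downstream_flipped", "discarded_fragment",
            "reason"]
    lines = ["\t".join(cols)]
    for d in result.diagnostics:
        lines.append("\t".join(str(d.get(c, "")) for c in cols))
    return "\n".join(lines) + "\n"
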