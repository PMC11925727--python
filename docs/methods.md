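# Methods

## The RGR model

An RGR (ribozyme–gRNA–ribozyme) cassette is the DNA-level composition

```
HH(stem + body) · guide_body · HDV
```

where `guide_body = spacer + sgRNA scaffold` for SpCas9 and
`direct repeat + spacer` for LbCas12a. The hammerhead's closing stem is the
reverse complement of the first six nucleotides of `guide_body` — the rule
is applied positionally to whatever follows the hammerhead's 3' end, not to
"the spacer". Consequently every LbCas12a cassette shares one stem (the
direct repeat is constant) while SpCas9 stems are guide-specific. If a
construct instead reorders the crRNA so the spacer abuts the hammerhead,
that is expressed here as registry-level configuration (swap the guide-body
order), not a code change.

Cassettes concatenate into a multiplex array, by default with no
inter-cassette linker (direct HDV→HH abutment); a linker is accepted and
accounted for in all coordinate bookkeeping.

## Cleavage simulation

Ribozyme chemistry is reduced to exact junction cuts: the hammerhead cuts
at its own 3' boundary (the released guide's 5' end is exact; the HH
byproduct keeps the stem, which is part of the ribozyme) and the HDV at its
own 5' boundary (guide 3' end exact). Nucleotide-level end chemistry
(2',3'-cyclic phosphate, 5'-OH) is deliberately not modeled; users for whom
trace end marks matter should treat released sequences as primary structure
only. Complete cleavage of an n-cassette transcript makes 2n cuts and
2n + 1 fragments; fragments always concatenate back to the transcript
(conservation is asserted in tests for every cut pattern). Partial
processing is modeled combinatorially through per-site boolean flags — no
kinetic rates are available to parameterize anything richer, and the
design claim being checked (guide identity is independent of the upstream
ORF, the trailer and neighboring cassettes) is a sequence property, not a
kinetic one.

## Type IIS cloning model

A double-stranded fragment is stored as the plus-strand image of its full
span plus the lengths of its 5' single-stranded extensions. At a left end a
5' overhang is a top-strand protrusion (a literal span prefix); at a right
end it is a bottom-strand protrusion stored via its plus-strand image (span
suffix). Two ends ligate exactly when their plus-strand images are equal
and non-empty; blunt ligation is not modeled, and overhang fidelity is
binary (no near-cognate mismatch ligation) — assembly is treated as
deterministic, which matches how a designed Golden Gate reaction is used.

Cut geometry is `(recognition, cut_offset_top, cut_offset_bottom)` in
nucleotides downstream of the recognition site on each strand; shipped
defaults are SapI (GCTCTTC 1/4, 3-nt overhangs; LguI aliased as its
isoschizomer) and BbsI (GAAGAC 2/6, 4-nt overhangs). Only 5'-overhang
enzymes are supported; a 3'-overhang geometry is rejected at registry load
with an explicit message. Digestion of a linear fragment with k internal
cuts yields k + 1 fragments (parent ends act as pseudo-cuts carrying the
existing overhangs); a circular fragment with k cuts yields k linear
fragments, origin-wrapping sites included. Overlapping cut windows raise an
error rather than guessing an order.

`golden_gate` models the one-pot reaction as its fixpoint: digest
everything to completion, discard any fragment still carrying a
recognition site (such a fragment can only produce a re-cuttable closure),
ligate exhaustively, and return the circular closures — which are
consequently free of the enzyme's sites. Circles are identified by their
canonical rotation, taken as the lexicographically smallest rotation over
*both* strands, so the construct set is invariant to input order and
orientation. The junction-graph search is capped (default 10,000 states)
because pathological overhang sets are user-constructible; hitting the cap
is an explicit error, never a silent truncation.

Directionality is enforced twice: overhang sets in the registry must be
pairwise distinct and non-self-complementary, and `add_cloning_arms`
additionally rejects `o5 == o3` and `o5 == revcomp(o3)` (which would admit
a flipped insert). Internal recognition sites inside a cassette are a
warning at build time and a hard error when arms are added — that is the
point where they become fatal.

## CRISPRa spacer enumeration

Candidates require a correctly placed PAM — NGG immediately 3' of the
protospacer for SpCas9, TTTV immediately 5' for LbCas12a, the PAM never
part of the spacer — and the entire protospacer inside the closed window
`[tss − max_upstream, tss − min_upstream]` in plus-strand coordinates
(defaults 300 and 75 bp upstream; both boundaries inclusive, so a
protospacer base exactly 75 or exactly 300 bp upstream is accepted and 74
or 301 is not). Whether a published window was measured to the protospacer
end, the PAM or the cut site is generally ambiguous; protospacer
containment was chosen as the most conservative reading and the bounds are
plain parameters. Both strands are searched (promoter-proximal CRISPRa
guides are routinely strand-agnostic); output is ordered by plus-strand
start, plus before minus, for deterministic files. Default spacer lengths
are 20 nt (SpCas9) and 23 nt (LbCas12a), configurable per call; accepted
spacer lengths are 18–25 nt. No on/off-target activity scoring is done —
that belongs to dedicated scoring tools, and this package orders candidates
by position only.

## Coordinates, alphabets, degenerate inputs

All internal coordinates are 0-based half-open; GenBank's 1-based inclusive
locations exist only at the file boundary (Biopython handles the
conversion). Sequences are uppercase-folded on construction and must be
unambiguous; IUPAC ambiguity codes are allowed only in motif patterns.
RNA→DNA conversion is always explicit, never silent. A palindromic motif
matching both strands over one interval is reported once, as a plus-strand
hit (one physical site). `reverse_complement("")` is `""` and motif scans
of empty or too-short sequences return empty lists — total functions where
harmless; empty *registry files*, by contrast, are errors.

## Synthetic fixtures

`generate_fixtures(seed, ...)` emulates the inputs of a real design
campaign: random spacers of both Cas systems (rejection-sampled to be free
of SapI/BbsI sites, as a designer would require), circular destination
vectors (default 400 bp — a scaled-down stand-in for a real plasmid, which
only adds inert backbone) carrying an inward-facing dropout wired to the
default overhang sets, and a 1 kb promoter with one SpCas9 and one LbCas12a
protospacer planted wholly inside the default window (at 200 and 150 bp
upstream of the TSS respectively). The same seed yields a byte-identical
bundle. What the fixtures do **not** emulate: real promoter base
composition (background is uniform random), chromatin or expression
context, repeat structure, and real vector features (origins, markers) —
so passing tests demonstrate the correctness of the design arithmetic and
assembly logic on realistic-scale sequences, not guide efficacy or cloning
yield in the lab.

## Illumination dose helper

For a pulsed regime (intensity I in mW/cm², on/off seconds, duration in
hours): duty = on/(on+off); total ON time = duty × duration; fluence
= I × total_on / 1000 J/cm². Defaults follow commonly used blue-light
regimes (1 mW/cm², 20 s ON with 40 or 60 s OFF, 470 nm); the wavelength is
carried as metadata only. Photochemical kinetics of the light-switchable
transcription factor are out of scope — no rate parameters are modeled.

## Problem sizes and determinism

The test suite fuzzes the stem rule over 1,000 cassettes, checks scanner
and digestion equivalence against independent brute-force oracles on
sequences up to 2 kb, and exhausts all 2^(2n) partial-cleavage patterns for
small n — sizes at which the brute-force oracles are trivially trustworthy
while still covering every code path. Hypothesis runs derandomized;
everything else is seeded. The acceptance script takes a single `--seed`
that drives every random choice.

## Known limitations

* Ribozyme folding is not verified: a spacer could in principle pair with
  ribozyme sequence and inhibit cleavage; thermodynamic screening of stems
  is out of scope, and cleavage is assumed complete unless flagged.
* Golden Gate fidelity is binary; ligase kinetics, star activity and
  methylation sensitivity are not modeled.
* Multi-enzyme one-pot reactions are not supported (one enzyme per
  assembly).
* The bundled part sequences are the field's standard defaults, not any
  specific vendor's or plasmid collection's exact parts; replace them via
  the registry for construct-exact output.
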