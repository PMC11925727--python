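# rgrkit

Design and in-silico validation of **ribozyme-flanked guide RNA (RGR)
cassettes** for CRISPR systems driven by RNA polymerase II promoters —
including light-inducible ones, where an optogenetic transcription factor
(e.g. a VPR–EL222 fusion acting on its cognate promoter) switches guide
production on with blue light.

## The problem

Guide RNAs are normally expressed from Pol III promoters, which cannot be
put under most inducible or tissue-specific control. An RGR cassette solves
this by embedding the guide in a Pol II transcript between two self-cleaving
ribozymes:

```
5' — [optional ORF, e.g. mCherry] — HH ribozyme — guide — HDV ribozyme — 3'
```

The hammerhead (HH) ribozyme cleaves at its own 3' boundary and the
hepatitis delta virus (HDV) ribozyme at its own 5' boundary, so the guide is
excised with exact 5' and 3' ends, and protein + guide(s) come off the same
transcript. Several cassettes on one transcript release several guides —
even for different Cas systems (SpCas9 sgRNAs and LbCas12a crRNAs) at once.

The one guide-specific design step is the **HH stem rule**: the first six
nucleotides of the hammerhead must be the reverse complement of the six
nucleotides immediately following the hammerhead's 3' end (helix I closes
against the nascent downstream RNA). For SpCas9 (spacer-first sgRNA) those
six nucleotides are the start of the spacer; for LbCas12a (repeat-first
crRNA) they are the start of the constant direct repeat.

`rgrkit` implements the complete workflow:

* **design** — build cassettes and multiplex arrays from spacer lists,
  applying the stem rule; enumerate CRISPRa candidate spacers in a promoter
  window (default 75–300 bp upstream of the TSS, NGG PAM for SpCas9, TTTV
  for LbCas12a);
* **simulate processing** — assemble the Pol II transcript and predict every
  fragment released by complete or partial ribozyme self-cleavage, in
  particular the exact released guide sequences;
* **simulate cloning** — add directional type IIS arms (SapI/LguI or BbsI),
  digest in silico, and verify one-pot Golden Gate assembly into a circular
  destination vector, junction by junction;
* **helpers** — FASTA/GenBank round trips, a YAML part registry, synthetic
  fixture generation, and pulsed-illumination dose arithmetic
  (duty cycle, total ON time, fluence).

The bundled ribozyme/scaffold sequences are the standard minimal hammerhead,
genomic HDV, SpCas9 sgRNA scaffold and LbCas12a direct repeat of the RGR
literature; swap in your own construct's exact parts via a registry YAML for
bit-exact output against a specific plasmid system.

## Worked example

```python
import rgrkit as rk

registry = rk.load_registry()

# two guides, one per Cas system, on one transcript
pdgfb = rk.Spacer("TTCACTCCCGGGCTCTGGCGGGC", "lbcas12a", "PDGFB_g1")
bmp2 = rk.Spacer("GCTGCGGTCGTTTCCGGCCA", "spcas9", "BMP2_g1")

array = rk.build_array([pdgfb, bmp2], registry)
for c in array.cassettes:
    print(f"{c.label}: stem={c.stem} cassette={len(c.full_sequence)} bp")

t = rk.assemble_transcript(array)
guides = rk.released_guides(rk.simulate_cleavage(t, "complete"))
for label, rna in guides:
    print(f"released {label}: {rna[:24]}... ({len(rna)} nt)")

enzyme = registry.get_enzyme("SapI")
armed = rk.add_cloning_arms(array, enzyme, ("AAT", "GCA"))
vector = rk.generate_fixtures(seed=1).vector_sapi
result = rk.golden_gate(vector, [armed.to_ds()], enzyme)
print(f"golden gate: {len(result.constructs)} construct(s), "
      f"{len(result.constructs[0].span)} bp, "
      f"{len(rk.find_sites(result.constructs[0].span, enzyme.recognition, 'both'))} SapI sites left")

duty, on_s, fluence = rk.illumination_dose(rk.IlluminationRegime(1.0, 20, 40, 1.0))
print(f"dose: duty={duty:.3f}, on={on_s:.0f} s, fluence={fluence:.2f} J/cm2")
```

prints

```
PDGFB_g1: stem=AAATTA cassette=155 bp
BMP2_g1: stem=CGCAGC cassette=207 bp
released PDGFB_g1: UAAUUUCUACUAAGUGUAGAUUUC... (44 nt)
released BMP2_g1: GCUGCGGUCGUUUCCGGCCAGUUU... (96 nt)
golden gate: 1 construct(s), 686 bp, 0 SapI sites left
dose: duty=0.333, on=1200 s, fluence=1.20 J/cm2
```

The Cas12a stem (`AAATTA`) pairs with the start of the constant direct
repeat — it is the same for every LbCas12a guide — while the Cas9 stem
(`CGCAGC`) pairs with the start of this particular spacer. Complete cleavage
of the two-cassette transcript releases exactly two guides, each byte-equal
to its guide body in RNA form: the crRNA leads with the direct repeat
(`UAAUUUCUACUAAGUGUAGAU…`), the sgRNA with its spacer. Golden Gate into the
fixture vector closes exactly one circle with no SapI site left, so the
assembly cannot re-cut.

The same pipelines are available from the shell via the `rgrkit` CLI
(`design`, `multiplex`, `arms`, `cleave`, `assemble`, `spacers`, `dose`,
`fixtures`; see `rgrkit --help`). Exit codes: 0 success, 2 validation
error, 3 design infeasible.

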