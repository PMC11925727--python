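# Default part registry.
#
# These are stand-in defaults: the minimal hammerhead and genomic HDV
# ribozymes of the RGR literature, the canonical SpCas9 sgRNA scaffold and
# the canonical LbCas12a direct repeat. Replace sequences with your own
# construct's exact parts (e.g. a vendor's supplementary sequences) for
# bit-exact output against a specific plasmid system.
#
# Schema (flat YAML):
#   parts:    list of {name, role, sequence}; role in
#             {hh_template, hdv, cas9_scaffold, cas12a_direct_repeat,
#              vector_arm}; the hh_template sequence must start with the
#             literal placeholder NNNNNN (replaced by the computed stem).
#   enzymes:  list of {name, recognition, cut_offset_top, cut_offset_bottom,
#             aliases?}; offsets are nt downstream of the recognition site
#             on each strand; bottom > top means 5' overhangs.
#   overhang_sets: mapping name -> ordered list of overhangs (plus-strand
#             image) used for directional insertion.

parts:
  - name: hh_minimal
    role: hh_template
    # first six nt (placeholder) pair with the six nt that follow the
    # ribozyme's 3' end, forming helix I of the hammerhead
    sequence: NNNNNNCTGATGAGTCCGTGAGGACGAAACGAGTAAGCTCGTC
  - name: hdv_genomic
    role: hdv
    sequence: GGCCGGCATGGTCCCAGCCTCCTCGCTGGCGCCGGCTGGGCAACATGCTTCGGCATGGCGAATGGGAC
  - name: sp_sgrna_scaffold
    role: cas9_scaffold
    sequence: GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC
  - name: lb_direct_repeat
    role: cas12a_direct_repeat
    sequence: TAATTTCTACTAAGTGTAGAT

enzymes:
  - name: SapI
    recognition: GCTCTTC
    cut_offset_top: 1
    cut_offset_bottom: 4
    aliases: [LguI]
  - name: BbsI
    recognition: GAAGAC
    cut_offset_top: 2
    cut_offset_bottom: 6

overhang_sets:
  sapi_default: [AAT, GCA]
  bbsi_default: [CACC, AAAC]
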