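# Default 7TM bundle frame: 200 Ballesteros-Weinstein positions over 7 helices.
#
# Each helix carries an inclusive BW index range and a partition into five
# horizontal sections, numbered 1 (extracellular) to 5 (intracellular).
# Because the chain alternates direction across the membrane,
# `extracellular_end` states which end of the ascending BW index range faces
# the extracellular side: "first" (odd helices, N-terminal end extracellular)
# or "last" (even helices).
#
# Helix III (3.22-3.55, sections 8/8/4/7/7) is fixed by the published
# combinatorics of its 34 intrahelical positions; the extreme section sizes
# (I-1 and VII-5 with 3 positions, VI-1 with 10, VII-1 with 9) are likewise
# fixed.  The remaining boundaries are editable defaults chosen so that the
# anchor residues *.50 and the conserved positions 1.52, 1.53, 2.46 and 3.43
# fall in section 4, the middle-to-intracellular band.
bundle_size: 200
helices:
  1: {start: 30, end: 60, sections: [3, 9, 9, 7, 3], extracellular_end: first}
  2: {start: 38, end: 67, sections: [6, 6, 6, 6, 6], extracellular_end: last}
  3: {start: 22, end: 55, sections: [8, 8, 4, 7, 7], extracellular_end: first}
  4: {start: 39, end: 62, sections: [5, 5, 5, 5, 4], extracellular_end: last}
  5: {start: 36, end: 63, sections: [6, 6, 6, 5, 5], extracellular_end: first}
  6: {start: 30, end: 60, sections: [10, 6, 5, 5, 5], extracellular_end: last}
  7: {start: 33, end: 54, sections: [9, 4, 3, 3, 3], extracellular_end: first}
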