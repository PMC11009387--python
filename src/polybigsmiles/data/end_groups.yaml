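# Reactive end-group pattern table for the AB-type split search.
#
# Each entry names a step-growth linkage and gives the conditions the two
# fragments of a decomposed repeat unit must fully match: `a` describes the
# first fragment, `b` the second.  `first`/`last` constrain the fragment's
# terminal backbone (attachment) atoms; a terminal spec may require the
# element, a carbonyl (double-bonded O on the atom), a neighboring element,
# and whether the atom may be aromatic (default: no).  `max_backbone`
# optionally caps the number of main-chain atoms in the fragment.
#
# Entries are tried in order; the first match wins.  The list is an
# editorial reconstruction of the common condensation end-group forms
# (diol, diamine, diacid, carbamate, carbonate) and can be extended or
# reordered by supplying a custom file.
- name: carbonate
  a:
    first: {element: O}
    last: {element: O}
  b:
    first: {element: C, carbonyl: true}
    last: {element: C, carbonyl: true}
    max_backbone: 1
- name: urethane
  a:
    first: {element: O}
    last: {element: O}
  b:
    first: {element: C, carbonyl: true, neighbor: N}
    last: {element: C, carbonyl: true, neighbor: N}
- name: ester
  a:
    first: {element: O}
    last: {element: O}
  b:
    first: {element: C, carbonyl: true}
    last: {element: C, carbonyl: true}
- name: amide
  a:
    first: {element: N}
    last: {element: N}
  b:
    first: {element: C, carbonyl: true}
    last: {element: C, carbonyl: true}
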