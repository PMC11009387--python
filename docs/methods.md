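# Methods

## Scope and model

The package converts between two line notations for homopolymers whose
repeat unit has exactly two polymerization points, written as asterisk
wildcards in SMILES. Asterisks are read strictly as polymerization points
(never as element wildcards), and each must be a monovalent, single-bonded
attachment: an asterisk with two neighbors (mid-chain) has no main-chain
remainder to swap with and the unit is rejected as unconvertible
(`no_main_chain`); an asterisk carrying an explicit non-single bond is
rejected as `unsupported_wildcard_bond`, since the homopolymer join is
assumed to be a single bond. Units with a number of points other than two
(multi-arm or graft architectures, plain molecules) are filtered out
before conversion.

## Equivalence oracles

Two keys, both canonical SMILES produced by RDKit, anchor every test:

- **unit key** — canonical form of the unit molecule itself. Invariant
  under reordering/renumbering of the same molecule.
- **cycle key** — the two wildcards are removed and their attachment atoms
  bonded together; the resulting ring molecule is canonicalized. A cyclic
  rotation ("parallel displacement") of a repeat unit cuts the same
  polymer backbone at a different bond, so every valid rotation shares one
  cycle key. Degenerate cases are tagged rather than forced: a
  single-atom backbone (both points on one atom) is keyed `loop|…`; when
  the closure would double an existing bond the bond order is promoted
  instead (the two-carbon unit closes to an ethylene-like key); closures
  that cannot be sanitized fall back to `unjoinable|` + unit key.

Aromatic-vs-kekulized spellings of the same structure (one published
ground-truth record writes an uppercase ring nitrogen) are absorbed by
RDKit's aromaticity perception inside canonicalization.

## Asterisk relocation

The permutative branch swap is retained as a string primitive
(`branch_swap_step`): the asterisk written as a branch exchanges roles
with the main-chain remainder to its right, ring labels are re-paired from
the original token sequence and re-assigned smallest-free-first (`%nn`
above 9), and the result is checked to preserve the unit key. The
pipeline itself (`relocate_asterisks`) relocates on the molecular graph:
the molecule is canonically renumbered, then written by a deterministic
traversal from one attachment atom to the other, so the asterisks land at
the ends *and* every spelling of the same unit yields one byte-identical
core. This canonical-traversal choice is what makes batch output
invariant to input ordering, which plain string surgery cannot guarantee.

Writer conventions, fixed for determinism: the main chain follows the
shortest path between the attachment atoms (ties resolved on canonical
atom ranks); side chains are parenthesized largest-first with the
continuation written last; ring bonds whose far end is reached through the
continuation are written as forward closure digits (the conventional
`C1CCCCC1` style), with labels allocated smallest-free-first; of the two
possible traversal directions the lexicographically smaller core wins,
comparing parentheses after letters so substituted carbons read `CC(...)`
rather than `C(...)C`. Every relocation is verified against the unit key
and raises rather than emitting a changed structure.

Stereo descriptors (`/`, `\`, `@`) are preserved verbatim by the string
primitives, and any rotation separating a stereo token from its atom is
invalid; the canonical relocation writer does not reproduce them (no
ground-truth record carries stereochemistry). This is a known limitation
for stereo-annotated inputs.

## Classification and assembly

The backbone is the ordered list of atoms outside all parentheses in the
core. All-C/Si backbones (aromatic carbon counts as carbon) are AA type —
polyolefins and polycarbosilanes, prepared by chain-growth routes — and
are wrapped as `{$core$}`. Everything else is AB. The rule reads the
repeat unit only; specialized synthesis conditions (e.g. catalytic routes
that change the mechanism) require manual post-adjustment and are out of
scope. Backbone atoms are compared by element symbol only; charges and
isotope labels do not change the AA/AB decision.

An AB backbone of exactly C,C,O (either reading direction; the unit is
re-oriented to start with carbon) triggers the ring-opening exception:
the unit is reversed and rotated back to a C,C,O backbone, and the pair is
emitted as `{<u1>,<u2>}` to express head-to-tail and tail-to-tail
placements. A symmetric unit (plain `CCO`) has no distinct second
orientation and is emitted as plain AB — the exception exists for
asymmetric epoxides.

Otherwise the end-group search rotates the core one character at a time,
k = 0 first, skipping shifts that break grammar or change the cycle key
(such shifts typically outnumber the parentheses plus ring digits in the
string). For each valid rotation the pattern table is tried in order, and
within an entry the leftmost token-boundary split wins; the first match
stops the search. `move_parallel` caps the displacement: −1 searches all
orderings, 0 only the unrotated core (useful for simulated datasets where
end groups rarely exist and speed matters), m > 0 searches up to shift m.
If no pair is found the output simply records the AB type, which is a
legitimate outcome (no homopolymer synthesis, or a structure too complex
to decompose).

### End-group pattern table

The published literature list behind the predefined end-group forms is
not enumerated anywhere, so the default table
(`polybigsmiles/data/end_groups.yaml`) is an editorial reconstruction of
the common condensation pairs — carbonate, carbamate (urethane), ester
(diol + diacid), amide (diamine + diacid) — expressed as anchored
constraints on a fragment's two terminal backbone atoms (element,
non-aromatic by default, carbonyl flag, required neighbor element,
optional backbone-length cap). Both fragment ends are anchored; there are
no partial or overlapping matches. The file format is documented in situ
and users can extend or reorder it; entry order is significant
(first match wins).

## BigSMILES parsing

Only the four homopolymer shapes the converter emits are recognized:
`{$u$}`, `{<u>}`, `{<A<,>B>}`, `{<u1>,<u2>}`. Fragments are validated as
SMILES with wildcards re-appended. Version-1.1 bracketed descriptors
(`[$]`, `[<]`, `[>]`) are accepted on input and normalized to the 1.0
forms emitted here; emitting 1.1 is out of scope. Back-conversion returns
`*u*` (AA, AB-plain), the concatenation `*AB*` (split — the two groups
re-join into one unit), or the first unit of a two-unit pair, which
carries the original orientation.

## Validation harness

Three procedures mirror the workflow's quality checks at fixture scale:
(1) converting each packaged reference SMILES must be structurally
equivalent (cycle key + AA/AB agreement) to its corrected BigSMILES;
(2) every conversion must round-trip (BigSMILES → SMILES → cycle key);
(3) seeded randomized reorderings (atom renumbering with a seeded RNG,
five per unit) must all convert to one identical string. The packaged
fixture CSV stores the eight corrected ground-truth rows exactly as
printed (typeset spaces included; normalization strips them at load),
the worked poly(ethylene adipate) example — printed without asterisks,
stored with them appended since the workflow requires two points — and
the polyoxytrimethylene rotation triple, whose expected output is derived
from this converter (the three spellings are the same polymer, asserted
via cycle key). The erroneous "obtained" strings ship as negative
fixtures: three are not syntactically feasible and must fail to parse;
the other five describe different polymers and must fail equivalence.

The synthetic-unit generator (`random_repeat_units`) assembles repeat
units from a small grammar of C/O/N backbones (1–8 heavy atoms), common
branches and occasional carbocycles, re-validated through the grammar
checker. It emulates the size range of published repeat units, not any
specific chemistry: passing round-trip tests on it demonstrates the
pipeline's invariants hold across arbitrary valid units, not that any
particular polymer class converts to a chemist-preferred decomposition.

## Problem sizes and numerics

Desk-scale runs use the 12 packaged fixtures, 100 generated units for
round-trip checks, five reorderings per unit for robustness, and
brute-force rotation enumeration for cores up to 30 characters (the
perfluorinated and terphenyl cores exceed this and are exercised through
the other procedures). The published multi-million-record conversions
require external downloads and are intentionally not reproduced; the
batch reader accepts such files (txt/csv/xlsx, 100 000-record csv chunks
with offset nomenclature, 85-character default length cutoff) when the
user supplies them. All randomness is seeded; reports and conversions
are deterministic given a seed.
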