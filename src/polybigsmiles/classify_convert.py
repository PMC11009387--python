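"""AA/AB classification, the ring-opening exception, end-group search and
BigSMILES assembly.

The polymerization type is read off the repeat unit's main chain (the atoms
outside all parentheses between the two attachment points):

- backbone of carbon/silicon only → **AA** type (chain-growth / addition;
  polyolefins and polycarbosilanes), written ``{$...$}``;
- anything else → **AB** type (step-growth / condensation), written
  ``{<...>}``.

Two AB refinements carry extra information into the notation:

- a backbone of exactly C,C,O marks a poly(alkylene oxide) made by ring
  opening of an (possibly asymmetric) epoxide, where head-to-tail and
  tail-to-tail placements both matter; such units are emitted as a pair
  ``{<u1>,<u2>}`` of the two unit orientations;
- otherwise a parallel-displacement search tries to cut the unit into two
  reactive end groups from a predefined pattern table (diol + diacid, …);
  success is written ``{<A<,>B>}``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import smiles_core as sc
from .errors import ContractViolation, RejectedInput
from .preprocess import RepeatUnit, filter_polymerization_points, \
    relocate_asterisks

__all__ = [
    "MainChain",
    "extract_main_chain",
    "classify",
    "detect_ring_opening",
    "make_two_unit_variant",
    "EndGroupPatternTable",
    "default_pattern_table",
    "EndGroupSplit",
    "find_end_groups",
    "PolymerClassification",
    "BigSmilesRecord",
    "assemble_bigsmiles",
    "convert",
]

_AA_ELEMENTS = {"C", "Si"}

_ELEMENT_RE = re.compile(r"\[\d*([A-Za-z][a-z]?)")


@dataclass(frozen=True)
class MainChain:
    """Ordered element symbols of the backbone atoms, aromatic flags kept."""

    atoms: tuple[tuple[str, bool], ...]  # (element, is_aromatic)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(e for e, _ in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)


def _token_element(tok: sc.Token) -> tuple[str, bool]:
    if tok.type is sc.TokenType.ATOM:
        return tok.text, False
    if tok.type is sc.TokenType.AROMATIC:
        return tok.text.upper(), True
    m = _ELEMENT_RE.match(tok.text)
    if not m:  # pragma: no cover - tokenizer guarantees shape
        raise ContractViolation(f"cannot read element from {tok.text!r}")
    sym = m.group(1)
    if sym.islower():
        return sym.upper(), True
    return sym, False


def extract_main_chain(unit: RepeatUnit | str) -> MainChain:
    """Backbone atoms of a core: atom tokens at branch depth zero, in order.

    Bond symbols and ring labels are excluded; wildcards must not appear in
    a core.
    """
    core = unit.core if isinstance(unit, RepeatUnit) else unit
    ts = sc.tokenize(core)
    depth = 0
    atoms = []
    for t in ts.tokens:
        if t.type is sc.TokenType.BRANCH_OPEN:
            depth += 1
        elif t.type is sc.TokenType.BRANCH_CLOSE:
            depth -= 1
        elif depth == 0 and t.is_atom:
            if t.type is sc.TokenType.WILDCARD:
                raise ContractViolation("core must be asterisk-stripped")
            atoms.append(_token_element(t))
    return MainChain(tuple(atoms))


def classify(mc: MainChain) -> str:
    """``"AA"`` iff every backbone element is carbon or silicon, else
    ``"AB"``.  Aromatic carbon counts as carbon."""
    if not len(mc):
        raise ContractViolation("empty main chain")
    return "AA" if all(e in _AA_ELEMENTS for e in mc.elements) else "AB"


def detect_ring_opening(mc: MainChain) -> bool:
    """True iff the backbone is exactly C,C,O (ring-opened epoxide).

    Cores are emitted carbon-end-first by preprocessing, but the reversed
    reading O,C,C is accepted too for robustness.
    """
    return mc.elements in (("C", "C", "O"), ("O", "C", "C"))


def _oriented_cco(core: str) -> str:
    """Rotate ``core`` so its backbone reads C,C,O."""
    if extract_main_chain(core).elements == ("C", "C", "O"):
        return core
    ref = sc.cycle_key(f"*{core}*")
    for k in range(1, len(core)):
        rot = sc.rotate_unit(core, k, ref)
        if rot.valid and \
                extract_main_chain(rot.text).elements == ("C", "C", "O"):
            return rot.text
    raise ContractViolation(f"no C,C,O orientation found for {core!r}")


def make_two_unit_variant(core: str) -> Optional[str]:
    """Alternate orientation of a ring-opened epoxide unit.

    The unit is reversed (traversed from the other terminal) and rotated
    until its backbone again reads C,C,O; together with ``core`` the pair
    expresses both head-to-tail and tail-to-tail configurations.  Returns
    None for a symmetric unit (e.g. plain ethylene oxide), whose reversal
    is not a distinct orientation.
    """
    core = _oriented_cco(core)
    reversed_unit = sc.reverse_unit(f"*{core}*")
    variant = _oriented_cco(reversed_unit[1:-1])
    if variant == core:
        return None
    if sc.cycle_key(f"*{variant}*") != sc.cycle_key(f"*{core}*"):
        raise ContractViolation("two-unit variant changed the polymer")
    return variant


# ---------------------------------------------------------------------------
# end-group pattern table

@dataclass(frozen=True)
class EndGroupPattern:
    name: str
    a: dict
    b: dict


@dataclass(frozen=True)
class EndGroupPatternTable:
    """Ordered reactive end-group pattern pairs; first match wins."""

    entries: tuple[EndGroupPattern, ...]

    def __post_init__(self):
        if not self.entries:
            raise ContractViolation("pattern table must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "EndGroupPatternTable":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(tuple(EndGroupPattern(e["name"], e["a"], e["b"])
                         for e in raw))


def default_pattern_table() -> EndGroupPatternTable:
    ref = resources.files("polybigsmiles.data") / "end_groups.yaml"
    with resources.as_file(ref) as path:
        return EndGroupPatternTable.from_yaml(Path(path))


def _atom_features(atom) -> dict:
    """Plain-data view of a terminal atom (safe to cache past mol lifetime)."""
    from rdkit import Chem
    return {
        "element": atom.GetSymbol(),
        "aromatic": atom.GetIsAromatic(),
        "carbonyl": any(b.GetBondType() == Chem.BondType.DOUBLE
                        and b.GetOtherAtom(atom).GetSymbol() == "O"
                        for b in atom.GetBonds()),
        "neighbors": {nb.GetSymbol() for nb in atom.GetNeighbors()},
    }


def _terminal_matches(feat: dict, spec: dict) -> bool:
    if feat["element"] != spec["element"]:
        return False
    if feat["aromatic"] != bool(spec.get("aromatic", False)):
        return False
    if spec.get("carbonyl") and not feat["carbonyl"]:
        return False
    if "neighbor" in spec and spec["neighbor"] not in feat["neighbors"]:
        return False
    return True


def _fragment_matches(frag: str, side: dict,
                      cache: dict) -> bool:
    """Does the whole fragment match one side template (both ends anchored)?"""
    info = cache.get(frag)
    if info is None:
        diag = sc.validate_grammar(f"*{frag}*")
        if not diag.ok:
            info = (None, None, 0)
        else:
            mol = sc.mol_from_smiles(f"*{frag}*")
            dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
            if len(dummies) != 2 or \
                    any(d.GetDegree() != 1 for d in dummies):
                info = (None, None, 0)
            else:
                first_d = min(dummies, key=lambda a: a.GetIdx())
                last_d = max(dummies, key=lambda a: a.GetIdx())
                info = (_atom_features(first_d.GetNeighbors()[0]),
                        _atom_features(last_d.GetNeighbors()[0]),
                        len(extract_main_chain(frag)))
        cache[frag] = info
    first, last, n_backbone = info
    if first is None:
        return False
    if "max_backbone" in side and n_backbone > side["max_backbone"]:
        return False
    return _terminal_matches(first, side["first"]) and \
        _terminal_matches(last, side["last"])


@dataclass(frozen=True)
class EndGroupSplit:
    group_a: str
    group_b: str
    pattern: str
    rotation_used: int


def _split_points(rotated: str) -> list[int]:
    """Character offsets where ``rotated`` may be cut into two fragments:
    token boundaries with balanced parentheses and paired ring labels on
    both sides."""
    try:
        ts = sc.tokenize(rotated)
    except Exception:
        return []
    points = []
    depth = 0
    ring_open: set[str] = set()
    for i, t in enumerate(ts.tokens):
        if t.type is sc.TokenType.BRANCH_OPEN:
            depth += 1
        elif t.type is sc.TokenType.BRANCH_CLOSE:
            depth -= 1
        elif t.type is sc.TokenType.RING:
            if t.text in ring_open:
                ring_open.discard(t.text)
            else:
                ring_open.add(t.text)
        if i + 1 < len(ts.tokens) and depth == 0 and not ring_open:
            points.append(ts.tokens[i + 1].position)
    return points


def find_end_groups(core: str, table: EndGroupPatternTable | None = None,
                    move_parallel: int = -1) -> Optional[EndGroupSplit]:
    """Search rotations of ``core`` for two seamlessly fitting end groups.

    Rotations are tried k = 0, 1, 2, ... (invalid shifts skipped); for each
    valid rotation the table entries are tried in order, and within an
    entry the leftmost split wins.  The search stops at the first match.
    ``move_parallel`` caps the displacement: -1 searches all orderings,
    0 only the unrotated string (faster on simulated data where end groups
    rarely exist), m > 0 searches shifts up to m.
    """
    if table is None:
        table = default_pattern_table()
    if move_parallel < 0:
        max_k = len(core) - 1
    else:
        max_k = min(move_parallel, len(core) - 1)
    ref = sc.cycle_key(f"*{core}*")
    cache: dict = {}
    for k in range(0, max_k + 1):
        rot = sc.rotate_unit(core, k, ref)
        if not rot.valid:
            continue
        points = _split_points(rot.text)
        for entry in table.entries:
            for p in points:
                a, b = rot.text[:p], rot.text[p:]
                if _fragment_matches(a, entry.a, cache) and \
                        _fragment_matches(b, entry.b, cache):
                    return EndGroupSplit(a, b, entry.name, k)
    return None


# ---------------------------------------------------------------------------
# assembly

@dataclass(frozen=True)
class PolymerClassification:
    """AA/AB decision with ring-opening and end-group annotations."""

    ptype: str                      # "AA" | "AB"
    ring_opening: bool = False
    split: Optional[EndGroupSplit] = None
    two_unit: Optional[str] = None  # alternate orientation, ring opening
    rotation_used: int = 0

    def __post_init__(self):
        if self.ring_opening and (self.ptype != "AB"
                                  or self.split is not None):
            raise ContractViolation(
                "ring opening implies AB type without an end-group split")
        if self.split is not None and self.ptype != "AB":
            raise ContractViolation("end-group split implies AB type")


@dataclass(frozen=True)
class BigSmilesRecord:
    """An assembled BigSMILES string tagged with its structural variant."""

    text: str
    variant: str  # "AA" | "AB_plain" | "AB_split" | "AB_two_unit"
    source_core: str
    classification: Optional[PolymerClassification] = field(
        default=None, compare=False)


def assemble_bigsmiles(cls: PolymerClassification,
                       core: str) -> BigSmilesRecord:
    """Wrap the core in the stochastic-object notation for its variant.

    The polymerization-point asterisks are replaced by curly brackets; AA
    units carry ``$`` descriptors, AB units angle brackets, split end
    groups the ``<,>`` separator and ring-opened pairs two ``<...>``
    objects.  Output contains no whitespace.
    """
    if cls.ptype == "AA":
        return BigSmilesRecord(f"{{${core}$}}", "AA", core, cls)
    if cls.split is not None:
        joined = cls.split.group_a + cls.split.group_b
        if sc.cycle_key(f"*{joined}*") != sc.cycle_key(f"*{core}*"):
            raise ContractViolation("split does not reassemble the unit")
        return BigSmilesRecord(
            f"{{<{cls.split.group_a}<,>{cls.split.group_b}>}}",
            "AB_split", core, cls)
    if cls.ring_opening and cls.two_unit is not None:
        return BigSmilesRecord(f"{{<{core}>,<{cls.two_unit}>}}",
                               "AB_two_unit", core, cls)
    return BigSmilesRecord(f"{{<{core}>}}", "AB_plain", core, cls)


def convert(s: str, table: EndGroupPatternTable | None = None,
            move_parallel: int = -1) -> BigSmilesRecord:
    """Full SMILES → BigSMILES pipeline for one repeat unit.

    normalize → two-point filter → asterisk relocation → AA/AB
    classification → ring-opening exception or end-group search →
    assembly.  Deterministic: equal inputs give equal outputs, and
    reordered spellings of the same unit give identical output strings.
    Raises :class:`RejectedInput` for filtered inputs.
    """
    norm = sc.normalize(s)
    screen = filter_polymerization_points(norm)
    screen.raise_if_rejected()
    unit = relocate_asterisks(norm)
    mc = extract_main_chain(unit)
    ptype = classify(mc)
    if ptype == "AA":
        return assemble_bigsmiles(PolymerClassification("AA"), unit.core)
    if detect_ring_opening(mc):
        core = _oriented_cco(unit.core)
        variant = make_two_unit_variant(core)
        if variant is None:
            return assemble_bigsmiles(
                PolymerClassification("AB"), core)
        return assemble_bigsmiles(
            PolymerClassification("AB", ring_opening=True,
                                  two_unit=variant), core)
    split = find_end_groups(unit.core, table, move_parallel)
    if split is not None:
        return assemble_bigsmiles(
            PolymerClassification("AB", split=split,
                                  rotation_used=split.rotation_used),
            unit.core)
    return assemble_bigsmiles(PolymerClassification("AB"), unit.core)
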