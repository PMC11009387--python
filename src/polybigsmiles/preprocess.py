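"""Filtering and asterisk relocation for repeat-unit SMILES.

Conversion to BigSMILES requires the two polymerization points at the two
ends of the string.  Most canonical SMILES spellings bury at least one
asterisk in a branch, so preprocessing (i) filters inputs to exactly two
grammar-valid polymerization points and (ii) relocates both asterisks to
the ends, producing the asterisk-stripped *core* whose ends are implied
attachment points.

Two relocation routes are provided:

- :func:`branch_swap_step` — the permutative string primitive: the
  mid-string asterisk (written as a branch) trades places with the
  main-chain remainder to its right, which becomes a branch in its stead;
  ring labels are renumbered so they stay paired.
- :func:`relocate_asterisks` — the pipeline entry point.  It canonicalizes
  the molecule internally (one canonical graph traversal between the two
  attachment atoms), which both relocates the asterisks and guarantees that
  differently-ordered spellings of the same unit produce an identical core.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from . import smiles_core as sc
from ._writer import canonical_renumber, orientation_key, write_core
from .errors import ContractViolation, RejectedInput

__all__ = [
    "ScreenResult",
    "filter_polymerization_points",
    "branch_swap_step",
    "RepeatUnit",
    "relocate_asterisks",
]


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the two-point filter."""

    accepted: bool
    reason: str | None = None
    n_wildcards: int | None = None

    def raise_if_rejected(self) -> None:
        if not self.accepted:
            detail = self.n_wildcards if self.reason == "wrong_point_count" \
                else None
            raise RejectedInput(self.reason, detail)


def filter_polymerization_points(s: str) -> ScreenResult:
    """Accept iff ``s`` has exactly two wildcards and valid grammar.

    Cases where the number of polymerization points differs from two are
    filtered out of the workflow here.
    """
    n = sc.wildcard_count(s)
    if n != 2:
        return ScreenResult(False, "wrong_point_count", n)
    if not sc.validate_grammar(s).ok:
        return ScreenResult(False, "invalid_grammar", n)
    return ScreenResult(True, None, n)


# ---------------------------------------------------------------------------
# token-level branch swap

def _find_wildcard(chain, parent=None):
    """Leftmost non-terminal wildcard as (owner_chain, index, parent_info).

    ``parent_info`` is ``(parent_chain, unit_index, branch_index)`` when the
    owner chain is a branch of some atom, else None.  Returns None when all
    wildcards are terminal on the main chain.
    """
    for j, u in enumerate(chain.units):
        if u.atom.type is sc.TokenType.WILDCARD:
            terminal = parent is None and j in (0, len(chain.units) - 1) \
                and not u.branches and not u.rings
            if not terminal:
                return chain, j, parent
        for bidx, br in enumerate(u.branches):
            found = _find_wildcard(_ChainView(br), (chain, j, bidx))
            if found:
                return found
    return None


class _ChainView:
    __slots__ = ("units",)

    def __init__(self, units):
        self.units = units


def _renumber_rings(original_tokens, new_text_chain):
    """Re-pair ring labels after units moved, assigning smallest free labels.

    Pairing is taken from the ORIGINAL token sequence (SMILES pairs a label's
    first occurrence with its second); labels in the rearranged text are then
    re-assigned in first-free order so every pair stays paired and
    non-colliding.
    """
    # pair ring tokens from the original linear order
    open_by_label: dict[str, sc.Token] = {}
    partner: dict[int, sc.Token] = {}
    for t in original_tokens:
        if t.type is sc.TokenType.RING:
            if t.text in open_by_label:
                other = open_by_label.pop(t.text)
                partner[id(t)] = other
                partner[id(other)] = t
            else:
                open_by_label[t.text] = t

    # walk the new chain in emission order, relabelling
    ring_text: dict[int, str] = {}
    assigned: dict[int, str] = {}
    free = list(range(1, 100))

    def label_text(n: int) -> str:
        return str(n) if n < 10 else f"%{n:02d}"

    def walk(units):
        for u in units:
            for _, ring in u.rings:
                mate = partner.get(id(ring))
                if mate is not None and id(mate) in assigned:
                    text = assigned.pop(id(mate))
                    free.append(int(text.lstrip("%")))
                    free.sort()
                    ring_text[id(ring)] = text
                else:
                    n = free.pop(0)
                    assigned[id(ring)] = label_text(n)
                    ring_text[id(ring)] = label_text(n)
            for br in u.branches:
                walk(br)

    walk(new_text_chain)
    return ring_text


def branch_swap_step(ts: sc.TokenizedSmiles | str) -> sc.TokenizedSmiles:
    """One permutative step: swap a mid-string asterisk with the main-chain
    remainder to the right of its parentheses.

    The targeted wildcard becomes terminal in its chain and the remainder
    becomes a branch in the slot the wildcard occupied.  Inputs whose
    wildcards are already terminal are returned unchanged; a wildcard with
    no main-chain remainder to swap with (a divalent, mid-chain attachment
    point) raises :class:`RejectedInput` with reason ``no_main_chain``.
    """
    if isinstance(ts, str):
        ts = sc.tokenize(sc.normalize(ts))
    chain = sc.parse_chain(ts.tokens)
    found = _find_wildcard(_ChainView(chain))
    if found is None:
        return ts
    owner, j, parent = found
    if parent is None or j != len(owner.units) - 1:
        # wildcard sits mid-chain: it would need two bonds, so there is no
        # main-chain remainder that can take its place
        raise RejectedInput("no_main_chain")
    pchain, i, bidx = parent
    x = pchain.units[i]
    remainder = pchain.units[i + 1:]
    before_w = owner.units[:-1]
    wild = owner.units[-1]
    if remainder:
        x.branches[bidx] = remainder
    else:
        del x.branches[bidx]
    pchain.units[i + 1:] = before_w + [wild]

    ring_text = _renumber_rings(ts.tokens, chain)
    new_text = sc.emit_chain(chain, ring_text)
    out = sc.tokenize(new_text)
    if sc.wildcard_count(new_text) == 2 and \
            sc.validate_grammar(new_text).ok:
        if sc.unit_key(new_text) != sc.unit_key(ts.source_text):
            raise ContractViolation(
                f"branch swap altered the molecule: {ts.source_text!r} -> "
                f"{new_text!r}")
    return out


# ---------------------------------------------------------------------------
# canonical relocation

@dataclass(frozen=True)
class RepeatUnit:
    """A preprocessed repeat unit.

    ``core`` is the asterisk-stripped string; re-appending ``*`` at both
    ends yields a grammar-valid unit with the same ``unit_key`` as the
    input.  ``relocation_steps`` counts how many asterisks had to be moved.
    """

    core: str
    n_wildcards_original: int = 2
    relocation_steps: int = 0

    @property
    def unit(self) -> str:
        return f"*{self.core}*"


def relocate_asterisks(s: str) -> RepeatUnit:
    """Relocate both asterisks to the ends, returning the canonical core.

    The input is canonicalized internally (canonical atom ranking followed
    by one deterministic traversal from one attachment atom to the other),
    so reordered spellings of the same unit give byte-identical cores.  The
    main chain of the emitted core lies outside all parentheses.
    """
    norm = sc.normalize(s)
    screen = filter_polymerization_points(norm)
    screen.raise_if_rejected()

    ts = sc.tokenize(norm)
    wpos = [i for i, t in enumerate(ts.tokens)
            if t.type is sc.TokenType.WILDCARD]
    steps = sum(1 for i in wpos if i not in (0, len(ts.tokens) - 1))

    mol = sc.mol_from_smiles(norm)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 0:
            continue
        if atom.GetDegree() != 1:
            raise RejectedInput(
                "no_main_chain",
                message="an asterisk sits mid-chain with no main-chain "
                        "remainder to swap with")
        bond = atom.GetBonds()[0]
        if bond.GetBondType() not in (Chem.BondType.SINGLE,
                                      Chem.BondType.UNSPECIFIED):
            raise RejectedInput("unsupported_wildcard_bond")

    mol = canonical_renumber(mol)
    dummies = sorted(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 0)
    cores = [write_core(mol, d) for d in dummies]
    core = min(cores, key=orientation_key)

    unit = f"*{core}*"
    if not sc.validate_grammar(unit).ok or \
            sc.unit_key(unit) != sc.unit_key(norm):
        raise ContractViolation(
            f"relocation failed to preserve the unit for {s!r} "
            f"(got {unit!r})")
    return RepeatUnit(core=core, n_wildcards_original=2,
                      relocation_steps=steps)
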