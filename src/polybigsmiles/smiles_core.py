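"""Tokenization, validation and equivalence oracles for repeat-unit SMILES.

A homopolymer repeat unit is a SMILES string carrying two polymerization
points written as asterisk wildcards, e.g. ``*CC(OC(=O)CCC)*``.  This module
provides the string-level primitives everything else builds on:

- :func:`normalize` — strip typeset whitespace, elide explicit single bonds,
  rewrite bracketed wildcards;
- :func:`tokenize` / :func:`detokenize` — lossless token view of a unit;
- :func:`validate_grammar` — lexical checks plus an RDKit parse;
- :func:`equivalence_key` — the pair of canonical keys used as oracles:
  ``unit_key`` identifies the repeat-unit *molecule*, ``cycle_key``
  identifies the *polymer* it generates (two units that are cyclic
  rotations of each other describe the same chain, so the key is computed
  on the molecule obtained by bonding the two attachment atoms together);
- :func:`reverse_unit` and :func:`rotate_unit` — the traversal-reversal and
  parallel-displacement (single-character cyclic shift) primitives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from rdkit import Chem, RDLogger

from .errors import ContractViolation, SmilesSyntaxError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "normalize",
    "Token",
    "TokenType",
    "TokenizedSmiles",
    "tokenize",
    "detokenize",
    "Diagnostics",
    "validate_grammar",
    "mol_from_smiles",
    "unit_key",
    "cycle_key",
    "EquivalenceKey",
    "equivalence_key",
    "reverse_unit",
    "rotate_unit",
    "wildcard_count",
]


# ---------------------------------------------------------------------------
# normalization

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")
_WS_RE = re.compile(r"\s+")
_BRACKET_WILDCARD_RE = re.compile(r"\[\d*\*\]")


def normalize(raw: str) -> str:
    """Normalize a raw SMILES string without checking validity.

    Removes all whitespace (published strings are typeset with spaces,
    e.g. ``"OCCOC( = O)CCCCC( = O)"``), maps unicode dashes to ``-`` and then
    drops explicit single-bond symbols outside of bracket atoms (the single
    bond is the SMILES default and is usually omitted), and rewrites
    bracketed wildcards such as ``[*]`` to the bare asterisk.  Everything
    else — bracket atoms, isotopes, charges — is preserved verbatim.
    """
    s = raw.translate(_DASHES)
    s = _WS_RE.sub("", s)
    s = _BRACKET_WILDCARD_RE.sub("*", s)
    out = []
    depth = 0
    for ch in s:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        if ch == "-" and depth == 0:
            continue
        out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# tokenization

class TokenType(Enum):
    ATOM = "atom"                # organic-subset atom, e.g. C, Cl, N
    AROMATIC = "aromatic"        # aromatic organic atom, e.g. c, n
    BRACKET = "bracket"          # bracket atom, e.g. [NH4+], [13C]
    BOND = "bond"                # - = # $ : / \
    BRANCH_OPEN = "branch_open"
    BRANCH_CLOSE = "branch_close"
    RING = "ring"                # single digit or %nn ring-closure label
    WILDCARD = "wildcard"        # * polymerization point


@dataclass(frozen=True)
class Token:
    type: TokenType
    text: str
    position: int

    @property
    def is_atom(self) -> bool:
        return self.type in (TokenType.ATOM, TokenType.AROMATIC,
                             TokenType.BRACKET, TokenType.WILDCARD)


_TOKEN_RE = re.compile(
    r"""(?P<bracket>\[[^\[\]]*\])
      | (?P<organic>Cl|Br|[BCNOPSFI])
      | (?P<aromatic>[bcnops])
      | (?P<wild>\*)
      | (?P<bond>[-=\#$:/\\])
      | (?P<open>\()
      | (?P<close>\))
      | (?P<ring>%\d{2}|\d)
    """,
    re.X,
)

_BRACKET_BODY_RE = re.compile(
    r"\[\d*(?:[A-Z][a-z]?|[a-z]{1,2}|\*)(?:@{1,2}|@TH\d|@AL\d|@SP\d)?"
    r"(?:H\d*)?(?:\+{1,3}|-{1,3}|[+-]\d+)?(?::\d+)?\]"
)


def _scan(s: str) -> tuple[list[Token], list[tuple[str, str, int | None]]]:
    """Lex ``s`` and collect structural diagnostics without raising."""
    tokens: list[Token] = []
    problems: list[tuple[str, str, int | None]] = []
    i = 0
    while i < len(s):
        m = _TOKEN_RE.match(s, i)
        if not m:
            problems.append(("lex", f"unrecognized character {s[i]!r}", i))
            i += 1
            continue
        kind = m.lastgroup
        text = m.group()
        ttype = {
            "bracket": TokenType.BRACKET,
            "organic": TokenType.ATOM,
            "aromatic": TokenType.AROMATIC,
            "wild": TokenType.WILDCARD,
            "bond": TokenType.BOND,
            "open": TokenType.BRANCH_OPEN,
            "close": TokenType.BRANCH_CLOSE,
            "ring": TokenType.RING,
        }[kind]
        if ttype is TokenType.BRACKET and not _BRACKET_BODY_RE.fullmatch(text):
            problems.append(("bracket", f"malformed bracket atom {text!r}", i))
        tokens.append(Token(ttype, text, i))
        i = m.end()

    depth = 0
    seen_atom = False
    prev: Token | None = None
    ring_counts: dict[str, int] = {}
    for t in tokens:
        if t.type is TokenType.BRANCH_OPEN:
            if prev is None or prev.type in (TokenType.BOND,
                                             TokenType.BRANCH_OPEN):
                problems.append(("branch", "branch opens without a preceding "
                                 "atom", t.position))
            depth += 1
        elif t.type is TokenType.BRANCH_CLOSE:
            depth -= 1
            if depth < 0:
                problems.append(("branch", "unbalanced branch close",
                                 t.position))
                depth = 0
            if prev is not None and prev.type is TokenType.BRANCH_OPEN:
                problems.append(("branch", "empty branch", t.position))
            if prev is not None and prev.type is TokenType.BOND:
                problems.append(("bond", "bond symbol before branch close",
                                 t.position))
        elif t.type is TokenType.RING:
            if not seen_atom or (prev is not None and prev.type in
                                 (TokenType.BRANCH_OPEN,)):
                problems.append(("ring", "ring label not attached to an atom",
                                 t.position))
            ring_counts[t.text] = ring_counts.get(t.text, 0) + 1
        elif t.type is TokenType.BOND:
            if prev is not None and prev.type is TokenType.BOND:
                problems.append(("bond", "consecutive bond symbols",
                                 t.position))
        if t.is_atom:
            seen_atom = True
        prev = t
    if depth != 0:
        problems.append(("branch", "unbalanced branch open", None))
    if prev is not None and prev.type is TokenType.BOND:
        problems.append(("bond", "dangling bond symbol", prev.position))
    for label, n in ring_counts.items():
        if n % 2:
            problems.append(("ring", f"dangling ring label {label!r}", None))
    return tokens, problems


@dataclass(frozen=True)
class TokenizedSmiles:
    """A repeat-unit SMILES as a validated token sequence."""

    tokens: tuple[Token, ...]
    source_text: str

    def detokenize(self) -> str:
        return "".join(t.text for t in self.tokens)

    def wildcard_positions(self) -> list[int]:
        """1-based token indices of wildcard tokens."""
        return [i + 1 for i, t in enumerate(self.tokens)
                if t.type is TokenType.WILDCARD]

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(s: str) -> TokenizedSmiles:
    """Tokenize a normalized SMILES string.

    Two-character organic atoms (``Cl``, ``Br``), bracket atoms and ``%nn``
    ring labels are single tokens.  Raises :class:`SmilesSyntaxError` naming
    the offending position for malformed bracket atoms, unbalanced
    parentheses or dangling ring labels.
    """
    tokens, problems = _scan(s)
    if problems:
        code, msg, pos = problems[0]
        raise SmilesSyntaxError(msg, pos)
    return TokenizedSmiles(tuple(tokens), s)


def detokenize(ts: TokenizedSmiles | Iterable[Token]) -> str:
    if isinstance(ts, TokenizedSmiles):
        return ts.detokenize()
    return "".join(t.text for t in ts)


def wildcard_count(s: str) -> int:
    tokens, _ = _scan(s)
    return sum(1 for t in tokens if t.type is TokenType.WILDCARD)


# ---------------------------------------------------------------------------
# grammar validation

@dataclass
class Diagnostics:
    """Outcome of :func:`validate_grammar`; truthy iff the string passed."""

    violations: list[tuple[str, str, int | None]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok

    def __repr__(self):
        return f"Diagnostics(ok={self.ok}, violations={self.violations!r})"


def validate_grammar(s: str) -> Diagnostics:
    """Check that ``s`` parses as a molecular graph.

    Wildcards are treated as monovalent attachment points.  Lexical and
    structural problems are reported with positions; if those pass, RDKit
    must accept (and sanitize) the string.  Diagnostics are the return
    value — this function does not raise.
    """
    _, problems = _scan(s)
    diag = Diagnostics(list(problems))
    if not diag.ok:
        return diag
    if s and Chem.MolFromSmiles(s) is None:
        diag.violations.append(("rdkit", "does not parse as a molecular "
                                "graph", None))
    return diag


def mol_from_smiles(s: str) -> Chem.Mol:
    """Parse with RDKit, raising :class:`SmilesSyntaxError` on failure."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise SmilesSyntaxError(f"RDKit cannot parse {s!r}")
    return mol


# ---------------------------------------------------------------------------
# equivalence oracles

@dataclass(frozen=True)
class EquivalenceKey:
    """Canonical identity of a two-point repeat unit.

    ``unit_key`` is the canonical SMILES of the unit molecule itself: equal
    for any two spellings of the same molecule.  ``cycle_key`` is the
    canonical SMILES of the molecule formed by bonding the two attachment
    atoms to each other; because a cyclic rotation of a repeat unit cuts the
    same polymer chain at a different bond, the cycle is invariant under any
    valid parallel displacement.
    """

    unit_key: str
    cycle_key: str


def _dummy_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def unit_key(s: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(s))


def cycle_key(s: str) -> str:
    """Rotation-invariant key: join the two attachment points, canonicalize.

    Degenerate units are keyed with a tag: a single-backbone-atom unit
    (both wildcards on one atom) would need a self-bond and is keyed as
    ``loop|``; a two-atom backbone whose closure doubles an existing bond is
    keyed by promoting that bond to the next order (the chain ``-C-C-``
    closed on itself is ethylene-like).
    """
    mol = mol_from_smiles(s)
    dummies = _dummy_atoms(mol)
    if len(dummies) != 2:
        raise ContractViolation(
            f"cycle_key needs exactly 2 wildcards, got {len(dummies)}")
    rw = Chem.RWMol(mol)
    nbrs = []
    for d in dummies:
        atom = rw.GetAtomWithIdx(d)
        neighbors = atom.GetNeighbors()
        if len(neighbors) != 1:
            raise ContractViolation(
                "wildcard is not a monovalent attachment point")
        nbrs.append(neighbors[0].GetIdx())
    n1, n2 = nbrs
    for d in sorted(dummies, reverse=True):
        if n1 > d:
            n1 -= 1
        if n2 > d:
            n2 -= 1
        rw.RemoveAtom(d)
    if n1 == n2:
        return "loop|" + Chem.MolToSmiles(rw.GetMol())
    bond = rw.GetBondBetweenAtoms(n1, n2)
    try:
        if bond is not None:
            order = {Chem.BondType.SINGLE: Chem.BondType.DOUBLE,
                     Chem.BondType.DOUBLE: Chem.BondType.TRIPLE}
            bond.SetBondType(order.get(bond.GetBondType(),
                                       Chem.BondType.SINGLE))
        else:
            rw.AddBond(n1, n2, Chem.BondType.SINGLE)
        joined = rw.GetMol()
        Chem.SanitizeMol(joined)
        return Chem.MolToSmiles(joined)
    except Exception:
        # chemically unjoinable ends; fall back to the unit identity
        return "unjoinable|" + unit_key(s)


def equivalence_key(s: str) -> EquivalenceKey:
    """Compute both keys; requires a grammar-valid unit with 2 wildcards."""
    diag = validate_grammar(s)
    if not diag.ok:
        raise ContractViolation(f"invalid SMILES {s!r}: {diag.violations}")
    n = wildcard_count(s)
    if n != 2:
        raise ContractViolation(f"expected exactly 2 wildcards, got {n}")
    return EquivalenceKey(unit_key(s), cycle_key(s))


# ---------------------------------------------------------------------------
# structural chain view (shared by reverse_unit and the branch swap)

@dataclass
class ChainUnit:
    """One main-chain position: its incoming bond, atom, ring labels and
    branches (each branch itself a chain)."""

    bond: str
    atom: Token
    rings: list[tuple[str, Token]] = field(default_factory=list)
    branches: list[list["ChainUnit"]] = field(default_factory=list)


def parse_chain(tokens: tuple[Token, ...]) -> list[ChainUnit]:
    """Parse a token sequence into the recursive chain structure."""
    chain, i = _parse_chain(tokens, 0, 0)
    if i != len(tokens):
        raise SmilesSyntaxError("unbalanced branch close",
                                tokens[i].position)
    return chain


def _parse_chain(tokens, i, depth):
    units: list[ChainUnit] = []
    pending_bond = ""
    while i < len(tokens):
        t = tokens[i]
        if t.type is TokenType.BRANCH_OPEN:
            if not units:
                raise SmilesSyntaxError("branch without preceding atom",
                                        t.position)
            sub, i = _parse_chain(tokens, i + 1, depth + 1)
            if i >= len(tokens) or tokens[i].type is not TokenType.BRANCH_CLOSE:
                raise SmilesSyntaxError("unbalanced branch open", t.position)
            units[-1].branches.append(sub)
            i += 1
        elif t.type is TokenType.BRANCH_CLOSE:
            if depth == 0:
                raise SmilesSyntaxError("unbalanced branch close", t.position)
            return units, i
        elif t.type is TokenType.BOND:
            if (i + 1 < len(tokens)
                    and tokens[i + 1].type is TokenType.RING):
                if not units:
                    raise SmilesSyntaxError("ring bond without atom",
                                            t.position)
                units[-1].rings.append((t.text, tokens[i + 1]))
                i += 2
            else:
                pending_bond = t.text
                i += 1
        elif t.type is TokenType.RING:
            if not units:
                raise SmilesSyntaxError("ring label without atom", t.position)
            units[-1].rings.append(("", t))
            i += 1
        elif t.is_atom:
            units.append(ChainUnit(pending_bond, t))
            pending_bond = ""
            i += 1
        else:  # pragma: no cover - all token types handled
            raise SmilesSyntaxError(f"unexpected token {t.text!r}", t.position)
    return units, i


def emit_chain(chain: list[ChainUnit],
               ring_text: dict[int, str] | None = None) -> str:
    """Serialize a chain back to SMILES text.

    ``ring_text`` optionally remaps ring-label tokens (by ``id``) to new
    label text, used by renumbering passes.
    """
    out: list[str] = []
    for u in chain:
        out.append(u.bond)
        out.append(u.atom.text)
        for bond, ring in u.rings:
            out.append(bond)
            out.append(ring.text if ring_text is None
                       else ring_text.get(id(ring), ring.text))
        for br in u.branches:
            out.append("(")
            out.append(emit_chain(br, ring_text))
            out.append(")")
    return "".join(out)


def reverse_unit(s: str) -> str:
    """Rewrite the unit as traversed from the opposite terminal.

    Requires wildcards at both string ends (the preprocessed form).  The
    main chain is reversed in place; branches are kept verbatim, and
    inter-atom bond symbols move with the bond they describe, so the
    molecule (``unit_key``) is preserved.
    """
    ts = tokenize(normalize(s))
    chain = parse_chain(ts.tokens)
    if (len(chain) < 2
            or chain[0].atom.type is not TokenType.WILDCARD
            or chain[-1].atom.type is not TokenType.WILDCARD
            or chain[-1].branches):
        raise ContractViolation(
            "reverse_unit requires wildcards at both ends")
    n = len(chain)
    rev: list[ChainUnit] = []
    for j in range(n - 1, -1, -1):
        u = chain[j]
        bond = chain[j + 1].bond if j + 1 < n else ""
        rev.append(ChainUnit(bond, u.atom, list(u.rings), list(u.branches)))
    out = emit_chain(rev)
    if unit_key(out) != unit_key(ts.source_text):
        raise ContractViolation(
            f"reversal changed the molecule for {s!r}")  # ring label clash
    return out


# ---------------------------------------------------------------------------
# parallel displacement

@dataclass(frozen=True)
class Rotation:
    """One candidate cyclic shift of an asterisk-stripped core."""

    text: str
    valid: bool
    k: int


def rotate_unit(core: str, k: int, reference_cycle_key: str | None = None
                ) -> Rotation:
    """Cyclically shift ``core`` by ``k`` characters and judge validity.

    The unit of displacement is a single character.  The shifted string is
    valid iff, with wildcards re-appended at both ends, it passes
    :func:`validate_grammar` *and* leaves the cycle key unchanged — a shift
    that strands a parenthesis breaks syntax, and one that moves a ring
    digit alone can describe a different structure; both are flagged, not
    raised.
    """
    if not 0 <= k < max(1, len(core)):
        raise ContractViolation(f"shift {k} out of range for {core!r}")
    text = core[k:] + core[:k]
    unit = f"*{text}*"
    if not validate_grammar(unit).ok:
        return Rotation(text, False, k)
    ref = reference_cycle_key or cycle_key(f"*{core}*")
    try:
        ok = cycle_key(unit) == ref
    except ContractViolation:
        ok = False
    return Rotation(text, ok, k)


def all_rotations(core: str) -> list[Rotation]:
    """All cyclic shifts of ``core`` with validity flags (k = 0..len-1)."""
    ref = cycle_key(f"*{core}*")
    return [rotate_unit(core, k, ref) for k in range(max(1, len(core)))]
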