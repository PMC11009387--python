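"""Two-terminal SMILES writer used by asterisk relocation.

Given a repeat-unit molecule with two monovalent dummy (wildcard) atoms,
emit an asterisk-stripped core string whose traversal starts at one
attachment atom and ends at the other, with the main chain kept outside all
parentheses.  The molecule is canonically renumbered first, so any input
spelling of the same unit yields the same core — this is what makes batch
conversion permutation-invariant.
"""

from __future__ import annotations

from rdkit import Chem

from .errors import ContractViolation

# orientation tie-break: compare cores with parentheses sorted after letters,
# so "CC(...)" beats "C(...)C" and atom symbols dominate the choice
_ORIENT_MAP = str.maketrans({"(": "\x7b", ")": "\x7c"})

_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_AROMATIC_PLAIN = {"B", "C", "N", "O", "P", "S"}


def orientation_key(core: str):
    return core.translate(_ORIENT_MAP)


def canonical_renumber(mol: Chem.Mol) -> Chem.Mol:
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = sorted(range(mol.GetNumAtoms()), key=lambda i: ranks[i])
    return Chem.RenumberAtoms(mol, order)


def _atom_token(atom: Chem.Atom) -> str:
    if atom.GetAtomicNum() == 0:
        return "*"
    sym = atom.GetSymbol()
    aromatic = atom.GetIsAromatic()
    charge = atom.GetFormalCharge()
    isotope = atom.GetIsotope()
    hs = atom.GetTotalNumHs()
    plain = (charge == 0 and isotope == 0
             and atom.GetNumRadicalElectrons() == 0 and sym in _ORGANIC)
    if plain and aromatic:
        if sym not in _AROMATIC_PLAIN or (sym != "C" and hs > 0):
            plain = False  # e.g. pyrrole-type [nH]
    if plain:
        return sym.lower() if aromatic else sym
    body = sym.lower() if aromatic else sym
    h = "" if hs == 0 else ("H" if hs == 1 else f"H{hs}")
    if charge > 0:
        c = "+" if charge == 1 else f"+{charge}"
    elif charge < 0:
        c = "-" if charge == -1 else f"-{-charge}"
    else:
        c = ""
    iso = str(isotope) if isotope else ""
    return f"[{iso}{body}{h}{c}]"


def _bond_token(bond: Chem.Bond) -> str:
    bt = bond.GetBondType()
    if bt in (Chem.BondType.SINGLE, Chem.BondType.AROMATIC):
        return ""
    if bt == Chem.BondType.DOUBLE:
        return "="
    if bt == Chem.BondType.TRIPLE:
        return "#"
    if bt == Chem.BondType.QUADRUPLE:
        return "$"
    raise ContractViolation(f"unsupported bond type {bt}")


class _RetryWithoutDeferral(Exception):
    pass


def write_core(mol: Chem.Mol, start_dummy: int) -> str:
    """Emit the core rooted at the attachment atom of ``start_dummy``.

    The main chain follows the shortest path between the two attachment
    atoms; side chains are parenthesized (largest subtree first) and ring
    bonds leaving the main chain become numbered closures.  A ring bond
    whose far end will be reached through the unparenthesized continuation
    is written as a forward closure digit (the conventional ``C1CCCCC1``
    style) rather than as a parenthesized branch.
    """
    try:
        return _write_core(mol, start_dummy, defer_ring_neighbors=True)
    except _RetryWithoutDeferral:
        return _write_core(mol, start_dummy, defer_ring_neighbors=False)


def _write_core(mol: Chem.Mol, start_dummy: int,
                defer_ring_neighbors: bool) -> str:
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 2:
        raise ContractViolation("writer needs exactly two wildcards")
    d2 = dummies[0] if dummies[1] == start_dummy else dummies[1]
    n1 = mol.GetAtomWithIdx(start_dummy).GetNeighbors()[0].GetIdx()
    n2 = mol.GetAtomWithIdx(d2).GetNeighbors()[0].GetIdx()
    excluded = {start_dummy, d2}

    if n1 == n2:
        path = (n1,)
    else:
        path = Chem.GetShortestPath(mol, n1, n2)
    path_set = set(path)
    nxt = {path[i]: path[i + 1] for i in range(len(path) - 1)}
    last = path[-1]

    size_cache: dict[tuple[int, int], int] = {}

    def reach_size(start: int, avoid: int) -> int:
        """Atoms reachable from ``start`` without passing ``avoid``."""
        key = (start, avoid)
        if key in size_cache:
            return size_cache[key]
        seen = {avoid, start} | excluded
        stack = [start]
        count = 1
        while stack:
            a = stack.pop()
            for b in mol.GetAtomWithIdx(a).GetNeighbors():
                bi = b.GetIdx()
                if bi not in seen:
                    seen.add(bi)
                    count += 1
                    stack.append(bi)
        size_cache[key] = count
        return count

    def reaches(start: int, target: int, avoid: int) -> bool:
        seen = {avoid, start} | excluded
        stack = [start]
        while stack:
            a = stack.pop()
            if a == target:
                return True
            for b in mol.GetAtomWithIdx(a).GetNeighbors():
                bi = b.GetIdx()
                if bi not in seen:
                    seen.add(bi)
                    stack.append(bi)
        return False

    visited: set[int] = set()
    ring_bonds: set[int] = set()
    emit_pos: dict[int, int] = {}
    # node: (atom_idx, [(kind, payload), ...]) where kind is "branch" or
    # "cont" (unparenthesized continuation); ring closures are collected
    # separately in ring_bonds
    def build(a: int, parent: int | None):
        visited.add(a)
        emit_pos[a] = len(emit_pos)
        children = []
        cands = [b.GetIdx() for b in mol.GetAtomWithIdx(a).GetNeighbors()
                 if b.GetIdx() not in excluded and b.GetIdx() != parent]
        if a == last:
            cont = None
        elif a in path_set:
            cont = nxt[a]
        else:
            tree_cands = [c for c in cands
                          if c not in visited and c not in path_set]
            cont = (max(tree_cands, key=lambda c: (reach_size(c, a), -c))
                    if tree_cands else None)
        par = [c for c in cands if c != cont]
        par.sort(key=lambda c: (-reach_size(c, a), c))
        for c in par + ([cont] if cont is not None else []):
            bond = mol.GetBondBetweenAtoms(a, c)
            # ring closure: neighbor already visited, a main-chain atom the
            # path will reach on its own, or (deferral) a neighbor the
            # continuation will reach anyway
            if c in visited or (c in path_set and c != nxt.get(a)) or \
                    (defer_ring_neighbors and c != cont and cont is not None
                     and reaches(c, cont, a)):
                if bond.GetIdx() not in ring_bonds:
                    ring_bonds.add(bond.GetIdx())
                    children.append(("ring", bond))
            elif c == cont:
                children.append(("cont", (bond, build(c, a))))
            else:
                children.append(("branch", (bond, build(c, a))))
        return (a, children)

    tree = build(n1, None)

    n_real = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() != 0)
    closure_ok = all(
        mol.GetBondWithIdx(bi).GetBeginAtomIdx() in emit_pos
        and mol.GetBondWithIdx(bi).GetEndAtomIdx() in emit_pos
        for bi in ring_bonds)
    if len(visited) != n_real or not closure_ok:
        if defer_ring_neighbors:
            raise _RetryWithoutDeferral
        raise ContractViolation("traversal failed to cover the unit")

    # ring closure digits: open at the first-emitted endpoint with the
    # smallest free label, free it at the partner
    ring_atom_tokens: dict[int, list[str]] = {}
    open_labels: dict[int, int] = {}
    free = list(range(1, 100))

    def ring_token(label: int) -> str:
        return str(label) if label < 10 else f"%{label:02d}"

    closures = sorted(
        ring_bonds,
        key=lambda bi: min(
            emit_pos[mol.GetBondWithIdx(bi).GetBeginAtomIdx()],
            emit_pos[mol.GetBondWithIdx(bi).GetEndAtomIdx()]))
    events: dict[int, list[tuple[int, int, str]]] = {}
    for bi in closures:
        bond = mol.GetBondWithIdx(bi)
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        first, second = sorted((a, b), key=lambda x: emit_pos[x])
        events.setdefault(first, []).append((emit_pos[second], bi,
                                             _bond_token(bond)))
        events.setdefault(second, []).append((emit_pos[first], bi, ""))

    def atom_ring_text(a: int) -> str:
        parts = []
        for _, bi, bondchar in sorted(events.get(a, [])):
            if bi in open_labels:
                label = open_labels.pop(bi)
                free.append(label)
                free.sort()
                parts.append(ring_token(label))
            else:
                label = free.pop(0)
                open_labels[bi] = label
                parts.append(bondchar + ring_token(label))
        return "".join(parts)

    def emit(node) -> str:
        a, children = node
        out = [_atom_token(mol.GetAtomWithIdx(a)), atom_ring_text(a)]
        for kind, payload in children:
            if kind == "ring":
                continue  # closures are emitted with the atom token
            bond, child = payload
            text = _bond_token(bond) + emit(child)
            out.append(f"({text})" if kind == "branch" else text)
        return "".join(out)

    return emit(tree)
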