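"""Packaged fixtures and the three technical-validation procedures.

The fixture set bundles the eight published ground-truth corrections
(reference SMILES + corrected BigSMILES, stored exactly as printed,
typeset spaces included), the in-text poly(ethylene adipate) worked
example, and the polyoxytrimethylene rotation triple.  The erroneous
"obtained" strings are kept as negative fixtures: each must either fail to
parse or fail structural equivalence against its correction.

Three runnable validation procedures mirror the conversion workflow's
quality checks:

1. **ground truth** — converting each reference SMILES yields a BigSMILES
   structurally equivalent to the corrected one;
2. **round trip** — BigSMILES converted back to SMILES describes the same
   polymer (cycle-key equality) as the input unit;
3. **robustness** — randomized reorderings of the same unit all convert to
   one identical BigSMILES string.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from rdkit import Chem

from . import smiles_core as sc
from .bigsmiles_parse import structurally_equivalent, to_smiles
from .classify_convert import convert
from .errors import PolyBigSmilesError

__all__ = [
    "FixtureRecord",
    "load_fixtures",
    "randomized_orderings",
    "random_repeat_units",
    "ValidationReport",
    "run_validation",
]


@dataclass(frozen=True)
class FixtureRecord:
    name: str
    reference_smiles: str
    expected_bigsmiles: str
    provenance: str                 # "table1" | "in_text" | "derived"
    index: Optional[int] = None
    erroneous_bigsmiles: Optional[str] = None
    note: str = ""

    @property
    def normalized_reference(self) -> str:
        return sc.normalize(self.reference_smiles)


def load_fixtures() -> list[FixtureRecord]:
    """All packaged fixtures (8 ground-truth corrections, the worked
    example, the rotation triple)."""
    ref = resources.files("polybigsmiles.data") / "table1_fixtures.csv"
    records = []
    with ref.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(FixtureRecord(
                name=row["name"],
                reference_smiles=row["reference_smiles"],
                expected_bigsmiles=row["corrected_bigsmiles"],
                provenance=row["source"],
                index=int(row["index"]) if row["index"] else None,
                erroneous_bigsmiles=row["obtained_bigsmiles"] or None,
                note=row["note"],
            ))
    return records


def table1_fixtures() -> list[FixtureRecord]:
    return [r for r in load_fixtures() if r.provenance == "table1"]


def randomized_orderings(s: str, n: int, seed: int) -> list[str]:
    """``n`` differently-ordered SMILES spellings of the same unit.

    Atom numbering is permuted with a seeded RNG and the molecule rewritten
    without canonicalization, so outputs are grammar-valid, unit-key-equal
    to ``s`` and reproducible; degenerate molecules may repeat spellings.
    """
    norm = sc.normalize(s)
    mol = sc.mol_from_smiles(norm)
    rng = random.Random(seed)
    out = []
    n_atoms = mol.GetNumAtoms()
    for _ in range(n):
        order = list(range(n_atoms))
        rng.shuffle(order)
        shuffled = Chem.RenumberAtoms(mol, order)
        out.append(sc.normalize(Chem.MolToSmiles(shuffled, canonical=False)))
    return out


_BACKBONE_ATOMS = ["C", "C", "C", "C", "O", "N"]
_BRANCHES = ["(C)", "(CC)", "(O)", "(C(C)C)", "(OC)", "(C(=O)C)", "(F)",
             "(Cl)", "(C(=O)OC)"]
_RINGS = ["C1CCCCC1", "C1CCCC1", "c1ccccc1"]


def random_repeat_units(n: int, seed: int) -> list[str]:
    """Seeded generator of valid two-point repeat units for stress tests.

    Units are assembled from a small grammar (C/O/N backbones, common
    branches, occasional carbocycles) and re-validated with the grammar
    checker; they emulate the size range of published homopolymer repeat
    units, not any particular chemistry.
    """
    rng = random.Random(seed)
    out = []
    while len(out) < n:
        length = rng.randint(1, 8)
        parts = []
        for i in range(length):
            if rng.random() < 0.08:
                parts.append(rng.choice(_RINGS))
                continue
            atom = rng.choice(_BACKBONE_ATOMS)
            parts.append(atom)
            if atom == "C" and rng.random() < 0.35:
                parts.append(rng.choice(_BRANCHES))
        unit = "*" + "".join(parts) + "*"
        if sc.validate_grammar(unit).ok and sc.wildcard_count(unit) == 2:
            out.append(unit)
    return out


@dataclass
class ValidationReport:
    procedure: int
    n: int = 0
    n_pass: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return self.n_pass == self.n


def run_validation(procedure: int,
                   records: Optional[Sequence[FixtureRecord]] = None,
                   seed: int = 0, n_orderings: int = 5) -> ValidationReport:
    """Run one validation procedure over fixture records.

    Procedure 1 counts ground-truth structural-equivalence matches (records
    without an expected BigSMILES are skipped); procedure 2 counts
    round-trip (BigSMILES → SMILES → cycle key) passes; procedure 3 counts
    units whose ``n_orderings`` seeded reorderings all convert to one
    identical string.
    """
    if procedure not in (1, 2, 3):
        raise ValueError("procedure must be 1, 2 or 3")
    if records is None:
        records = load_fixtures()
    report = ValidationReport(procedure)
    for i, rec in enumerate(records):
        ref = rec.normalized_reference
        try:
            if procedure == 1:
                if not rec.expected_bigsmiles:
                    continue
                report.n += 1
                ok = structurally_equivalent(
                    convert(ref).text, rec.expected_bigsmiles)
            elif procedure == 2:
                report.n += 1
                back = to_smiles(convert(ref).text)
                ok = sc.cycle_key(back) == sc.cycle_key(ref)
            else:
                report.n += 1
                outputs = {convert(o).text for o in
                           randomized_orderings(ref, n_orderings,
                                                seed + i)}
                outputs.add(convert(ref).text)
                ok = len(outputs) == 1
        except PolyBigSmilesError as exc:
            ok = False
            report.failures.append(f"{rec.name}: {exc}")
        if ok:
            report.n_pass += 1
        elif not report.failures or \
                not report.failures[-1].startswith(rec.name):
            report.failures.append(f"{rec.name}: mismatch")
    return report
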