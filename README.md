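# polybigsmiles

Automated, bidirectional conversion between repeat-unit **SMILES** and
**BigSMILES** for homopolymers with two polymerization points.

SMILES describes a small molecule; a polymer repeat unit is usually written
as a SMILES fragment whose two attachment positions carry asterisk
wildcards, e.g. `*CC(OC(=O)CCC)*` for poly(vinyl butyrate). BigSMILES wraps
the polymeric fragment in a stochastic object whose bonding descriptors add
information SMILES cannot express: the polymerization mechanism, the
relevance of head-to-tail vs tail-to-tail placement, and the identity of
the two reactive end groups of a step-growth polymer. This package
automates the conversion for the homopolymer case, so that large SMILES
collections can be annotated for machine-learning work without manual
curation, and converts BigSMILES back to SMILES for interchangeability
checks. It is aimed at polymer-informatics practitioners who need the
notation, and ships the validation harness used to establish that the
conversion is faithful.

## The conversion in brief

1. **Filter** — inputs must carry exactly two polymerization points
   (`*`) and parse as a molecular graph (RDKit).
2. **Relocate** — both asterisks are moved to the string ends. The
   mid-string asterisk, written as a branch, trades places with the
   main-chain remainder to its right (the permutative branch swap);
   internally the unit is canonicalized so every spelling of the same unit
   yields one core string with the main chain outside all parentheses.
3. **Classify** — if the backbone (atoms outside all parentheses between
   the two attachment points) contains only C or Si, the polymer is **AA
   type** (chain growth / addition) and written `{$core$}`. Anything else
   is **AB type** (step growth / condensation), written `{<core>}`.
4. **Ring-opening exception** — an AB backbone of exactly C,C,O marks a
   ring-opened (possibly asymmetric) epoxide, where both head-to-tail and
   tail-to-tail placements matter; the unit and its reversed orientation
   are emitted as a pair `{<u1>,<u2>}`.
5. **End-group search** — otherwise the core is cyclically shifted one
   character at a time (parallel displacement; shifts that break syntax or
   change the polymer are skipped) until the string splits into two
   reactive end groups from a configurable pattern table (diol + diacid,
   diamine + diacid, carbamate, carbonate); success is written
   `{<A<,>B>}`.

Equivalence of two representations is judged on the *cycle key*: bonding
the two attachment atoms of a unit to each other gives a ring molecule
that is invariant under any valid displacement of the unit, so two strings
denote the same polymer iff their cycles canonicalize identically.

## Worked example

```python
>>> from polybigsmiles import convert, to_smiles
>>> convert("*CC(*)(C)C(=O)OCC(C)C").text      # poly(isobutyl methacrylate)
'{$CC(C(=O)OCC(C)C)(C)$}'
>>> convert("*OCCOC( = O)CCCCC( = O)*").text   # poly(ethylene adipate)
'{<OCCO<,>C(=O)CCCCC(=O)>}'
>>> convert("*CC(COC)O*").text                 # poly(3-methoxypropylene oxide)
'{<CC(COC)O>,<C(COC)CO>}'
>>> to_smiles('{<OCCO<,>C(=O)CCCCC(=O)>}')
'*OCCOC(=O)CCCCC(=O)*'
```

The first output's `$` descriptors state that the methacrylate polymerizes
through identical reactive ends (AA, chain growth). The adipate output
separates its two condensation end groups — the diol `OCCO` and the
diacid `C(=O)CCCCC(=O)` — with the `<,>` marker. The epoxide-derived
polyether is emitted as two units, the original and the reversed
orientation, because head-to-tail and tail-to-tail placement both matter
for asymmetric epoxides. Back-conversion reassembles the repeat unit.

Batch work goes through the CLI:

```
polybigsmiles convert --input units.csv --outdir converted/
polybigsmiles validate            # run the three validation procedures
polybigsmiles fixtures            # print the packaged ground-truth table
```

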