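source,index,name,reference_smiles,obtained_bigsmiles,corrected_bigsmiles,note
table1,28,Poly(3-methoxypropylene oxide),*CC(COC)O*,"{<CC(OC)O>, <C(OC)CO>}","{<CC(COC)O>, <C(COC)CO>}",
table1,65,Perfluoropolymer:poly[2-(1-{[dodecafluoro-6-(2-2-2-trifluoroethoxy)hexyl]oxy}-tetrafluoroethyl)-4-methyl-1-3-5-triazine],*c1nc(C)nc(C(F)(OC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)OC(*)C(F)(F)F)C(F)(F)F)n1,{<C(C(F)(F)F)OC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)OC(F)(C(F)(F)F)c1nc(nc(C)n1)>},{<c1nc(C)nc(n1)C(F)(C(F)(F)F)OC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)OC(C(F)(F)F)>},
table1,69,Perfluoropolymer:poly[2-(2-2-2-trifluoro-1-{[tetradecafluoro-7-(2-2-2-trifluoroethoxy)heptyl]oxy}ethyl)-4-(trifluoromethyl)-1-3-5-triazine],*C(C(F)(F)F)OC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)OC(C(F)(F)F)c1nc(nc(C(F)(F)F)n1)*,{<C(C(F)(F)F)OC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)OC(C(F)(F)F)c1nc(nc(C(F)(F)F)n)>},{<C(C(F)(F)F)OC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)OC(C(F)(F)F)c1nc(nc(C(F)(F)F)n1)>},
table1,78,Poly(vinyl butyrate),*CC(OC( = O)CCC)*,{$CC(OC( = O)CCC$},{$CC(OC( = O)CCC)$},
table1,113,Poly(isobutyl methacrylate),*CC(*)(C)C( = O)OCC(C)C,{$CC(C)(C( = O)CC(C)C)$},{$CC(C( = O)OCC(C)C)(C)$},
table1,192,Poly(cyclohexyl alpha-chloroacrylate),*CC(*)(Cl)C( = O)OC1CCCCC1,{$CC(C( = O)C1CCCCC1)(Cl)$},{$CC(C( = O)OC1CCCCC1)(Cl)$},
table1,236,Poly(N-vinyl carbazole),*CC(*)n1c2ccccc2c2ccccc21,{$CC(N1c2c(cccc2)c3c1(cccc3)$},{$CC(N1c2c(cccc2)c3ccccc13)$},
table1,283,Poly(quinoxaline-2-7-diylquinoxaline-7-2-diyl-p-terphenyl-4-4'-ylene),*c1ccc(-c2ccc(-c3ccc(-c4cnc5ccc(-c6ccc7ncc(*)nc7c6)cc5n4)cc3)cc2)cc1,"{<c1nc2cc(ccc2nc1)c3cc4nc(cnc4cc3)<, >c1ccc(cc1)c2ccc(cc2)c3c(cccc3)>}",{<c1ccc(cc1)c2ccc(cc2)c3ccc(cc3)c4cnc5ccc(cc5n4)c6ccc7ncc(nc7c6)>},
in_text,,Poly(ethylene adipate),*OCCOC( = O)CCCCC( = O)*,,"{<OCCO <, > C( = O)CCCCC( = O) >}",worked example; printed without asterisks — polymerization points appended at both ends
derived,,Polyoxytrimethylene,*CCCO*,,{<CCCO>},rotation triple member; expected output derived from this converter
derived,,Polyoxytrimethylene (shift 1),*CCOC*,,{<CCCO>},rotation triple member; same polymer by parallel displacement
derived,,Polyoxytrimethylene (shift 2),*COCC*,,{<CCCO>},rotation triple member; same polymer by parallel displacement
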