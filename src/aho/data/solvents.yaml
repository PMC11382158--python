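# Solvent normalization table (editable). Keys are canonical labels; values
# are synonyms, abbreviations, and SMILES that map onto them. Matching is
# case-insensitive on the stripped string.
dichloromethane: [DCM, CH2Cl2, ClCCl, C(Cl)Cl, methylene chloride]
methanol: [MeOH, CH3OH, CO, OC]
ethanol: [EtOH, CCO, OCC, C2H5OH]
2-propanol: [IPA, iPrOH, i-PrOH, isopropanol, CC(C)O, CC(O)C]
tert-butanol: [tBuOH, t-BuOH, CC(C)(C)O]
trifluoroethanol: [TFE, CF3CH2OH, OCC(F)(F)F, FC(F)(F)CO]
toluene: [PhMe, MePh, Cc1ccccc1, c1ccccc1C]
tetrahydrofuran: [THF, C1CCOC1, C1CCCO1]
1,4-dioxane: [dioxane, C1COCCO1]
ethyl acetate: [EtOAc, AcOEt, CCOC(C)=O, CC(=O)OCC]
1,2-dichloroethane: [DCE, ClCCCl]
hexane: [n-hexane, CCCCCC]
benzene: [PhH, c1ccccc1]
water: [H2O, O]
diethyl ether: [Et2O, ether, CCOCC]
acetonitrile: [MeCN, CH3CN, CC#N]
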