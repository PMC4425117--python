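CC   -----------------------------------------------------------------------
CC   Mini extract in the ExPASy ENZYME flat-file dialect, bundled for
CC   offline annotation and reporting. Covers the EC numbers of the gut
CC   microbiome comparative study plus representative alternative-name
CC   collisions and transferred/deleted entries.
CC   -----------------------------------------------------------------------
ID   1.1.1.1
DE   Alcohol dehydrogenase.
AN   Aldehyde reductase.
CA   (1) a primary alcohol + NAD(+) = an aldehyde + NADH.
CA   (2) a secondary alcohol + NAD(+) = a ketone + NADH.
//
ID   1.1.1.21
DE   Aldose reductase.
AN   Aldehyde reductase.
CA   An alditol + NAD(P)(+) = an aldose + NAD(P)H.
//
ID   1.1.1.70
DE   Deleted entry.
//
ID   1.2.7.3
DE   2-oxoglutarate synthase.
AN   2-ketoglutarate ferredoxin oxidoreductase.
CA   2-oxoglutarate + CoA + 2 oxidized ferredoxin = succinyl-CoA + CO2 + 2
CA   reduced ferredoxin + 2 H(+).
//
ID   1.4.1.14
DE   Glutamate synthase (NADH).
AN   NADH-dependent glutamate synthase.
CA   2 L-glutamate + NAD(+) = L-glutamine + 2-oxoglutarate + NADH.
//
ID   1.8.1.2
DE   Sulfite reductase (NADPH).
CA   H2S + 3 NADP(+) + 3 H2O = sulfite + 3 NADPH.
//
ID   1.8.99.1
DE   Transferred entry: 1.8.1.2 and 1.8.7.1.
//
ID   1.8.99.3
DE   Hydrogensulfite reductase.
CA   (O3S.S.SO3)(2-) + acceptor + 2 H2O + OH(-) = 3 HSO3(-) + reduced
CA   acceptor.
//
ID   1.11.1.1
DE   NADH peroxidase.
CA   NADH + H2O2 = NAD(+) + 2 H2O.
//
ID   1.11.1.9
DE   Glutathione peroxidase.
CA   2 glutathione + H2O2 = glutathione disulfide + 2 H2O.
//
ID   1.15.1.2
DE   Superoxide reductase.
CA   Superoxide + reduced rubredoxin + 2 H(+) = H2O2 + rubredoxin.
//
ID   1.16.1.1
DE   Mercury(II) reductase.
CA   Hg + NADP(+) + H(+) = Hg(2+) + NADPH.
//
ID   2.1.1.10
DE   Homocysteine S-methyltransferase.
CA   S-methyl-L-methionine + L-homocysteine = 2 L-methionine.
//
ID   2.1.1.14
DE   5-methyltetrahydropteroyltriglutamate--homocysteine
DE   S-methyltransferase.
AN   Methionine synthase (cobalamin-independent).
CA   5-methyltetrahydropteroyltri-L-glutamate + L-homocysteine =
CA   tetrahydropteroyltri-L-glutamate + L-methionine.
//
ID   2.1.1.77
DE   Protein-L-isoaspartate(D-aspartate) O-methyltransferase.
CA   S-adenosyl-L-methionine + protein L-isoaspartate =
CA   S-adenosyl-L-homocysteine + protein L-isoaspartate alpha-methyl ester.
//
ID   2.1.1.176
DE   16S rRNA (cytosine(967)-C(5))-methyltransferase.
CA   S-adenosyl-L-methionine + cytosine(967) in 16S rRNA =
CA   S-adenosyl-L-homocysteine + 5-methylcytosine(967) in 16S rRNA.
//
ID   2.6.1.11
DE   Acetylornithine transaminase.
AN   Acetylornithine aminotransferase.
CA   N(2)-acetyl-L-ornithine + 2-oxoglutarate = N-acetyl-L-glutamate
CA   5-semialdehyde + L-glutamate.
//
ID   2.6.1.44
DE   Alanine--glyoxylate transaminase.
CA   L-alanine + glyoxylate = pyruvate + glycine.
//
ID   2.6.1.52
DE   Phosphoserine transaminase.
CA   (1) O-phospho-L-serine + 2-oxoglutarate = 3-phosphonooxypyruvate +
CA   L-glutamate. (2) 4-phosphonooxy-L-threonine + 2-oxoglutarate =
CA   (3R)-3-hydroxy-2-oxo-4-phosphonooxybutanoate + L-glutamate.
//
ID   2.8.1.1
DE   Thiosulfate sulfurtransferase.
AN   Rhodanese.
CA   Thiosulfate + cyanide = sulfite + thiocyanate.
//
ID   2.8.1.2
DE   3-mercaptopyruvate sulfurtransferase.
CA   3-mercaptopyruvate + cyanide = pyruvate + thiocyanate.
//
ID   3.5.3.1
DE   Arginase.
CA   L-arginine + H2O = L-ornithine + urea.
//
ID   3.8.1.2
DE   (S)-2-haloacid dehalogenase.
CA   (S)-2-haloacid + H2O = (R)-2-hydroxyacid + halide.
//
ID   3.8.1.5
DE   Haloalkane dehalogenase.
CA   1-haloalkane + H2O = a primary alcohol + halide.
//
ID   3.8.1.9
DE   (R)-2-haloacid dehalogenase.
CA   (R)-2-haloacid + H2O = (S)-2-hydroxyacid + halide.
//
ID   3.8.1.10
DE   2-haloacid dehalogenase (configuration-inverting).
CA   (1) (S)-2-haloacid + H2O = (R)-2-hydroxyacid + halide. (2)
CA   (R)-2-haloacid + H2O = (S)-2-hydroxyacid + halide.
//
ID   4.1.1.22
DE   Histidine decarboxylase.
CA   L-histidine = histamine + CO2.
//
ID   4.1.1.50
DE   Adenosylmethionine decarboxylase.
CA   S-adenosyl-L-methionine = S-adenosyl 3-(methylthio)propylamine + CO2.
//
ID   4.2.1.22
DE   Cystathionine beta-synthase.
CA   L-serine + L-homocysteine = L-cystathionine + H2O.
//
ID   4.4.1.1
DE   Cystathionine gamma-lyase.
CA   L-cystathionine + H2O = L-cysteine + NH3 + 2-oxobutanoate.
//
ID   4.4.1.8
DE   Cystathionine beta-lyase.
CA   L-cystathionine + H2O = L-homocysteine + NH3 + pyruvate.
//
ID   4.4.1.11
DE   Methionine gamma-lyase.
CA   L-methionine + H2O = methanethiol + NH3 + 2-oxobutanoate.
//
ID   5.1.1.12
DE   Ornithine racemase.
CA   L-ornithine = D-ornithine.
//
ID   5.4.3.5
DE   D-ornithine 4,5-aminomutase.
CA   D-ornithine = (2R,4S)-2,4-diaminopentanoate.
//
ID   6.3.2.2
DE   Glutamate--cysteine ligase.
AN   Gamma-glutamylcysteine synthetase.
CA   ATP + L-glutamate + L-cysteine = ADP + phosphate +
CA   gamma-L-glutamyl-L-cysteine.
//
ID   6.3.2.3
DE   Glutathione synthase.
AN   Glutathione synthetase.
CA   ATP + gamma-L-glutamyl-L-cysteine + glycine = ADP + phosphate +
CA   glutathione.
//
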