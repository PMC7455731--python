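name	smiles	superclass
hexanoic acid	CCCCCC(=O)O	Lipids and lipid-like molecules
octanoic acid	CCCCCCCC(=O)O	Lipids and lipid-like molecules
decanoic acid	CCCCCCCCCC(=O)O	Lipids and lipid-like molecules
lauric acid	CCCCCCCCCCCC(=O)O	Lipids and lipid-like molecules
myristic acid	CCCCCCCCCCCCCC(=O)O	Lipids and lipid-like molecules
palmitic acid	CCCCCCCCCCCCCCCC(=O)O	Lipids and lipid-like molecules
stearic acid	CCCCCCCCCCCCCCCCCC(=O)O	Lipids and lipid-like molecules
arachidic acid	CCCCCCCCCCCCCCCCCCCC(=O)O	Lipids and lipid-like molecules
behenic acid	CCCCCCCCCCCCCCCCCCCCCC(=O)O	Lipids and lipid-like molecules
lignoceric acid	CCCCCCCCCCCCCCCCCCCCCCCC(=O)O	Lipids and lipid-like molecules
oleic acid	CCCCCCCC/C=C\CCCCCCCC(=O)O	Lipids and lipid-like molecules
linoleic acid	CCCCC/C=C\C/C=C\CCCCCCCC(=O)O	Lipids and lipid-like molecules
palmitoleic acid	CCCCCC/C=C\CCCCCCCC(=O)O	Lipids and lipid-like molecules
myristoleic acid	CCCC/C=C\CCCCCCCC(=O)O	Lipids and lipid-like molecules
monopalmitin	CCCCCCCCCCCCCCCC(=O)OCC(O)CO	Lipids and lipid-like molecules
monoolein	CCCCCCCC/C=C\CCCCCCCC(=O)OCC(O)CO	Lipids and lipid-like molecules
cholesterol	CC(C)CCCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)O)C)C	Lipids and lipid-like molecules
testosterone	CC12CCC3C(C1CCC2O)CCC4=CC(=O)CCC34C	Lipids and lipid-like molecules
estradiol	CC12CCC3C(C1CCC2O)CCC4=C3C=CC(=C4)O	Lipids and lipid-like molecules
progesterone	CC(=O)C1CCC2C1(CCC3C2CCC4=CC(=O)CCC34C)C	Lipids and lipid-like molecules
cortisol	CC12CCC(=O)C=C1CCC3C2C(CC4(C3CCC4(C(=O)CO)O)C)O	Lipids and lipid-like molecules
dehydroepiandrosterone	CC12CCC3C(C1CCC2=O)CC=C4C3(CCC(C4)O)C	Lipids and lipid-like molecules
glycine	NCC(=O)O	Organic acids and derivatives
alanine	CC(N)C(=O)O	Organic acids and derivatives
serine	OCC(N)C(=O)O	Organic acids and derivatives
proline	OC(=O)C1CCCN1	Organic acids and derivatives
valine	CC(C)C(N)C(=O)O	Organic acids and derivatives
threonine	CC(O)C(N)C(=O)O	Organic acids and derivatives
leucine	CC(C)CC(N)C(=O)O	Organic acids and derivatives
isoleucine	CCC(C)C(N)C(=O)O	Organic acids and derivatives
asparagine	NC(=O)CC(N)C(=O)O	Organic acids and derivatives
glutamine	NC(=O)CCC(N)C(=O)O	Organic acids and derivatives
lysine	NCCCCC(N)C(=O)O	Organic acids and derivatives
methionine	CSCCC(N)C(=O)O	Organic acids and derivatives
histidine	OC(=O)C(N)Cc1c[nH]cn1	Organic acids and derivatives
phenylalanine	NC(Cc1ccccc1)C(=O)O	Organic acids and derivatives
arginine	NC(=N)NCCCC(N)C(=O)O	Organic acids and derivatives
tyrosine	NC(Cc1ccc(O)cc1)C(=O)O	Organic acids and derivatives
tryptophan	NC(Cc1c[nH]c2ccccc12)C(=O)O	Organic acids and derivatives
citric acid	OC(=O)CC(O)(CC(=O)O)C(=O)O	Organic acids and derivatives
succinic acid	OC(=O)CCC(=O)O	Organic acids and derivatives
malic acid	OC(CC(=O)O)C(=O)O	Organic acids and derivatives
fumaric acid	OC(=O)/C=C/C(=O)O	Organic acids and derivatives
lactic acid	CC(O)C(=O)O	Organic acids and derivatives
glutathione	NC(CCC(=O)NC(CS)C(=O)NCC(=O)O)C(=O)O	Organic acids and derivatives
creatine	CN(CC(=O)O)C(=N)N	Organic acids and derivatives
glucose	OCC1OC(O)C(O)C(O)C1O	Organic oxygen compounds
fructose	OCC1(O)OCC(O)C(O)C1O	Organic oxygen compounds
ribose	OCC1OC(O)C(O)C1O	Organic oxygen compounds
xylose	OCC1OC(O)C(O)C1O	Organic oxygen compounds
sucrose	OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O	Organic oxygen compounds
maltose	OCC1OC(OC2C(CO)OC(O)C(O)C2O)C(O)C(O)C1O	Organic oxygen compounds
glycerol	OCC(O)CO	Organic oxygen compounds
sorbitol	OCC(O)C(O)C(O)C(O)CO	Organic oxygen compounds
myo-inositol	OC1C(O)C(O)C(O)C(O)C1O	Organic oxygen compounds
N-acetylglucosamine	CC(=O)NC1C(O)OC(CO)C(O)C1O	Organic oxygen compounds
gluconic acid	OCC(O)C(O)C(O)C(O)C(=O)O	Organic oxygen compounds
benzoic acid	OC(=O)c1ccccc1	Benzenoids
salicylic acid	OC(=O)c1ccccc1O	Benzenoids
vanillin	COc1cc(C=O)ccc1O	Benzenoids
hydroquinone	Oc1ccc(O)cc1	Benzenoids
phenol	Oc1ccccc1	Benzenoids
paracetamol	CC(=O)Nc1ccc(O)cc1	Benzenoids
aspirin	CC(=O)Oc1ccccc1C(=O)O	Benzenoids
4-hydroxybenzoic acid	OC(=O)c1ccc(O)cc1	Benzenoids
gallic acid	OC(=O)c1cc(O)c(O)c(O)c1	Benzenoids
phenylacetic acid	OC(=O)Cc1ccccc1	Benzenoids
hippuric acid	OC(=O)CNC(=O)c1ccccc1	Benzenoids
tyramine	NCCc1ccc(O)cc1	Benzenoids
cinnamic acid	OC(=O)/C=C/c1ccccc1	Phenylpropanoids and polyketides
ferulic acid	COc1cc(/C=C/C(=O)O)ccc1O	Phenylpropanoids and polyketides
caffeic acid	OC(=O)/C=C/c1ccc(O)c(O)c1	Phenylpropanoids and polyketides
p-coumaric acid	OC(=O)/C=C/c1ccc(O)cc1	Phenylpropanoids and polyketides
quercetin	Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O	Phenylpropanoids and polyketides
kaempferol	Oc1ccc(-c2oc3cc(O)cc(O)c3c(=O)c2O)cc1	Phenylpropanoids and polyketides
naringenin	Oc1ccc(C2CC(=O)c3c(O)cc(O)cc3O2)cc1	Phenylpropanoids and polyketides
catechin	Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2	Phenylpropanoids and polyketides
resveratrol	Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1	Phenylpropanoids and polyketides
6-hydroxycoumarin	Oc1ccc2oc(=O)ccc2c1	Phenylpropanoids and polyketides
umbelliferone	Oc1ccc2ccc(=O)oc2c1	Phenylpropanoids and polyketides
cardamonin	COc1cc(O)c(C(=O)/C=C/c2ccccc2)c(O)c1	Phenylpropanoids and polyketides
adenine	Nc1ncnc2[nH]cnc12	Organoheterocyclic compounds
guanine	Nc1nc2[nH]cnc2c(=O)[nH]1	Organoheterocyclic compounds
hypoxanthine	O=c1[nH]cnc2[nH]cnc12	Organoheterocyclic compounds
xanthine	O=c1[nH]c(=O)c2[nH]cnc2[nH]1	Organoheterocyclic compounds
uracil	O=c1cc[nH]c(=O)[nH]1	Organoheterocyclic compounds
thymine	Cc1c[nH]c(=O)[nH]c1=O	Organoheterocyclic compounds
cytosine	Nc1cc[nH]c(=O)n1	Organoheterocyclic compounds
caffeine	Cn1c(=O)c2c(ncn2C)n(C)c1=O	Organoheterocyclic compounds
theobromine	Cn1cnc2c1c(=O)[nH]c(=O)n2C	Organoheterocyclic compounds
nicotinamide	NC(=O)c1cccnc1	Organoheterocyclic compounds
indole	c1ccc2[nH]ccc2c1	Organoheterocyclic compounds
serotonin	NCCc1c[nH]c2ccc(O)cc12	Organoheterocyclic compounds
melatonin	COc1ccc2[nH]cc(CCNC(C)=O)c2c1	Organoheterocyclic compounds
allopurinol	O=c1[nH]cnc2n[nH]cc12	Organoheterocyclic compounds
adenosine	Nc1ncnc2c1ncn2C1OC(CO)C(O)C1O	Nucleosides, nucleotides, and analogues
guanosine	Nc1nc2c(ncn2C2OC(CO)C(O)C2O)c(=O)[nH]1	Nucleosides, nucleotides, and analogues
uridine	OCC1OC(n2ccc(=O)[nH]c2=O)C(O)C1O	Nucleosides, nucleotides, and analogues
cytidine	Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1	Nucleosides, nucleotides, and analogues
inosine	OCC1OC(n2cnc3c(=O)[nH]cnc32)C(O)C1O	Nucleosides, nucleotides, and analogues
adenosine monophosphate	Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O	Nucleosides, nucleotides, and analogues
thymidine	Cc1cn(C2CC(O)C(CO)O2)c(=O)[nH]c1=O	Nucleosides, nucleotides, and analogues
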