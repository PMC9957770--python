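name,full_name,formula,kind,tag_warning
5-HT,serotonin,C10H12N2O,amine,none
5-HTP,5-hydroxy-L-tryptophan,C11H12N2O3,alpha_amino_acid,none
AABA,2-aminobutyric acid,C4H9NO2,alpha_amino_acid,none
Ala,alanine,C3H7NO2,alpha_amino_acid,none
Arg,arginine,C6H14N4O2,alpha_amino_acid,none
Asn,asparagine,C4H8N2O3,alpha_amino_acid,none
Asp,aspartic acid,C4H7NO4,alpha_amino_acid,none
BABA,beta-aminobutyric acid,C4H9NO2,amine,none
Cys,cysteine,C3H7NO2S,alpha_amino_acid,none
DA,dopamine,C8H11NO2,amine,none
DOPA,L-DOPA,C9H11NO4,alpha_amino_acid,none
GABA,gamma-aminobutyric acid,C4H9NO2,amine,none
Gln,glutamine,C5H10N2O3,alpha_amino_acid,cyclizes
Glu,glutamic acid,C5H9NO4,alpha_amino_acid,none
Gly,glycine,C2H5NO2,alpha_amino_acid,none
His,histidine,C6H9N3O2,alpha_amino_acid,none
Ile,isoleucine,C6H13NO2,alpha_amino_acid,none
Leu,leucine,C6H13NO2,alpha_amino_acid,none
Lys,lysine,C6H14N2O2,alpha_amino_acid,none
Met,methionine,C5H11NO2S,alpha_amino_acid,none
O-MTY,O-methyl-tyrosine,C10H13NO3,alpha_amino_acid,none
Phe,phenylalanine,C9H11NO2,alpha_amino_acid,none
Pro,proline,C5H9NO2,alpha_amino_acid,none
SAM,S-adenosyl methionine,C15H22N6O5S,other,no_stable_ketone
Ser,serine,C3H7NO3,alpha_amino_acid,none
Thr,threonine,C4H9NO3,alpha_amino_acid,none
Trp,tryptophan,C11H12N2O2,alpha_amino_acid,none
Tym,tyramine,C8H11NO,amine,none
Tyr,tyrosine,C9H11NO3,alpha_amino_acid,none
Val,valine,C5H11NO2,alpha_amino_acid,none
beta-Ala,beta-alanine,C3H7NO2,amine,none
alpha-KG,alpha-ketoglutarate,C5H6O5,keto_acid,none
pyruvate,pyruvic acid,C3H4O3,keto_acid,none
phenylpyruvate,phenylpyruvic acid,C9H8O3,keto_acid,none
MTOB,4-methylthio-2-oxobutanoate,C5H8O3S,keto_acid,none
I5P,imidazol-5-yl-pyruvate,C6H6N2O3,keto_acid,none
4-HPP,4-hydroxyphenylpyruvate,C9H8O4,keto_acid,none
OAA,oxaloacetate,C4H4O5,keto_acid,none
4M2OP,4-methyl-2-oxopentanoate,C6H10O3,keto_acid,none
alpha-KB,2-oxobutanoate,C4H6O3,keto_acid,none
glyoxylate,glyoxylic acid,C2H2O3,keto_acid,none
hydroxypyruvate,hydroxypyruvic acid,C3H4O4,keto_acid,none
3M2OB,3-methyl-2-oxobutanoate,C5H8O3,keto_acid,none
3M2OP,3-methyl-2-oxopentanoate,C6H10O3,keto_acid,none
IPA,indole-3-pyruvate,C11H9NO3,keto_acid,none
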