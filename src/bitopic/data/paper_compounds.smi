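CNC1Cc2ccccc2C1	1
Cc1cccc2sc(NC(=O)CCCCN(C)C3Cc4ccccc4C3)nc12	2
COc1cccc2sc(NC(=O)CCCCN(C)C3Cc4ccccc4C3)nc12	18
CN(CCCCC(=O)Nc1nc2c(Cl)cccc2s1)C1Cc2ccccc2C1	19
CN(CCCCC(=O)Nc1nc2c(Br)cccc2s1)C1Cc2ccccc2C1	20
CCN(CCCCC(=O)Nc1nc2c(OC)cccc2s1)C1Cc2ccccc2C1	21
CCN(CCCCC(=O)Nc1nc2c(Br)cccc2s1)C1Cc2ccccc2C1	22
CCCN(CCCCC(=O)Nc1nc2c(F)cccc2s1)C1Cc2ccccc2C1	23
CCCN(CCCCC(=O)Nc1nc2c(CC)cccc2s1)C1Cc2ccccc2C1	24
CCCN(CCCCC(=O)Nc1nc2c(C)cccc2s1)C1Cc2ccccc2C1	25
CCCN(CCCCC(=O)Nc1nc2c(OC)cccc2s1)C1Cc2ccccc2C1	26
CCCN(CCCCC(=O)Nc1nc2c(Br)cccc2s1)C1Cc2ccccc2C1	27
CCCN(CCCCC(=O)Nc1nc2c(OC)ccc(Cl)c2s1)C1Cc2ccccc2C1	28
CCCN(CCCCC(=O)Nc1nc2c(OC)ccc(C)c2s1)C1Cc2ccccc2C1	29
CCCN(CCCCC(=O)Nc1nc2c(OC)ccc(OC)c2s1)C1Cc2ccccc2C1	30
CN(CCCCN)C1Cc2ccccc2C1	synthon_CH3_butylamine
CN(CCCCC(=O)O)C1Cc2ccccc2C1	synthon_CH3_pentanamide
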