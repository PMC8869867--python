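protein_id	category	subcategory
PSMA1	UPS	20S alpha
PSMA2	UPS	20S alpha
PSMA3	UPS	20S alpha
PSMA4	UPS	20S alpha
PSMA5	UPS	20S alpha
PSMA6	UPS	20S alpha
PSMA7	UPS	20S alpha
PSMB1	UPS	20S beta
PSMB2	UPS	20S beta
PSMB3	UPS	20S beta
PSMB4	UPS	20S beta
PSMB5	UPS	20S beta
PSMB6	UPS	20S beta
PSMB7	UPS	20S beta
PSMC1	UPS	19S base
PSMC2	UPS	19S base
PSMC3	UPS	19S base
PSMC4	UPS	19S base
PSMC5	UPS	19S base
PSMC6	UPS	19S base
PSMD1	UPS	19S base
PSMD2	UPS	19S base
PSMD4	UPS	19S base
ADRM1	UPS	19S base
PSMD3	UPS	19S lid
PSMD6	UPS	19S lid
PSMD7	UPS	19S lid
PSMD8	UPS	19S lid
PSMD11	UPS	19S lid
PSMD12	UPS	19S lid
PSMD13	UPS	19S lid
PSMD14	UPS	19S lid
ULK1	ALS	early signaling
ATG13	ALS	early signaling
RB1CC1	ALS	early signaling
AMBRA1	ALS	early signaling
MTOR	ALS	early signaling
BECN1	ALS	early signaling
ATG5	ALS	autophagosome formation
ATG7	ALS	autophagosome formation
ATG12	ALS	autophagosome formation
ATG16L1	ALS	autophagosome formation
MAP1LC3B	ALS	autophagosome formation
WIPI2	ALS	autophagosome formation
SQSTM1	ALS	autophagosome formation
STX17	ALS	lysosome fusion
SNAP29	ALS	lysosome fusion
VAMP8	ALS	lysosome fusion
LAMP1	ALS	lysosome fusion
LAMP2	ALS	lysosome fusion
RAB7A	ALS	lysosome fusion
VPS33A	ALS	lysosome fusion
VTI1A	ALS	lysosome fusion
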