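BRCANESS_34	Synthetic stand-in 34-gene BRCAness panel (BRCA1-mutation-associated DNA-repair and proliferation genes); not the original published list	AURKA	AURKB	BLM	BUB1	CCNB1	CCNB2	CDC20	CDC45	CDK1	CENPA	CHEK1	EXO1	FANCA	FANCI	FOXM1	KIF2C	KIF4A	MCM2	MCM10	MELK	NEK2	ORC1	PLK1	POLQ	PSMD2	PTTG1	RAD51	RAD54L	RRM2	TRIP13	TTK	TYMS	UBE2C	UHRF1
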