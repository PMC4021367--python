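amino_acid	supply	demand	to_others	from_others	remark
alanine	0.7399	0.355	0.3853	0	surplus alanine contributes to glycine synthesis
glycine	0.116	0.308	0	0.1918	partly produced from alanine
valine	0.224	0.109	0.1151	0	excess valine used for anteiso fatty-acid synthesis
leucine	1.427	0.244	1.1827	0	excess leucine used for iso-C15:0 and iso-C17:0 fatty-acid synthesis
isoleucine	0.5181	0.039	0.4794	0	excess isoleucine used for anteiso fatty-acid synthesis
proline	-0.24	0.189	0	0.4291	synthesized from glutamate
methionine	0.015	0.015	0	0	consumed exactly at biosynthetic demand
serine	0.057	0.135	0	0.0785	partly synthesized from glycine
threonine	0.03	0.100	0	0.0699	partly synthesized from aspartate
phenylalanine	0.086	0.086	0	0	consumed exactly at biosynthetic demand
aspartate	-0.12	0.103	0	0.2232	synthesized from oxaloacetate and glutamate
cysteine	0.0087	0.009	0	0	consumed exactly at biosynthetic demand
glutamate	1.48	0.176	1.3041	0	excess glutamate feeds other amino-acid synthesis
arginine	-0.93	0.211	0	1.1409	synthesized from aspartate
asparagine	-0.023	0.103	0	0.1262	synthesized from aspartate
lysine	-0.141	0.087	0	0.2283	synthesized from oxoglutarate
glutamine	0	0.177	0	0.1771	synthesized from glutamate
histidine	0	0.024	0	0.0245	synthesized from PRPP
tyrosine	-0.03204	0.069	0	0.1007	synthesized from PEP and E4P
tryptophan	-0.01116	0.043	0	0.0538	synthesized from serine
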