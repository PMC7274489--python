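# Residue groups for the 26-d physicochemical encoder (v1).
# 21 group-composition components in this row order, followed by the
# 5 atomic fractions (C, H, N, O, S). Groups may overlap across rows.
group	residues
acidic	DE
basic	KRH
neutral_charge	ACFGILMNPQSTVWY
hydrophobic	CLVIMFW
hydrophilic	RKEDQN
neutral_hydropathy	GASTPHY
aromatic	FWYH
aliphatic	AGILV
polar	RKEDQNHSTY
nonpolar	ACFGILMPVW
tiny	ACGST
small	ACDGNPSTV
large	EFHIKLMQRWY
sulfur_containing	CM
amide	NQ
hydroxyl	STY
positively_charged	KR
negatively_charged	DE
proline	P
glycine	G
cysteine	C
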