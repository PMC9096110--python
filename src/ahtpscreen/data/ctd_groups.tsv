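# Three-group residue partitions for the seven CTD physicochemical
# properties (Dubchak-style groupings). Property order is fixed:
# hydrophobicity, normwaalsvolume, polarity, polarizability, charge,
# secondarystruct, solventaccess. v1
property	group	residues
hydrophobicity	1	RKEDQN
hydrophobicity	2	GASTPHY
hydrophobicity	3	CLVIMFW
normwaalsvolume	1	GASTPDC
normwaalsvolume	2	NVEQIL
normwaalsvolume	3	MHKFRYW
polarity	1	LIFWCMVY
polarity	2	PATGS
polarity	3	HQRKNED
polarizability	1	GASDT
polarizability	2	CPNVEQIL
polarizability	3	KMHFRYW
charge	1	KR
charge	2	ANCQGHILMFPSTWYV
charge	3	DE
secondarystruct	1	EALMQKRH
secondarystruct	2	VIYCWFT
secondarystruct	3	GNPSD
solventaccess	1	ALFCGIVW
solventaccess	2	RKQEND
solventaccess	3	MSPTHY
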