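# model_name	unified_label
Hpt	Hpt
HPT	Hpt
P2	P2/CheY-binding
CheY-binding	P2/CheY-binding
H-kinase_dim	H-kinase_dim
H_kinase_dim	H-kinase_dim
HATPase_c	HATPase_c
CheW	CheW
CheW_2	CheW
Response_reg	CheY-like
CheY-like	CheY-like
CheC	CheC/CheX
CheX	CheC/CheX
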