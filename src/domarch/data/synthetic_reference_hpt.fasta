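>synthetic_hpt_ref synthetic 130-aa Hpt-like reference; phospho-accepting histidine at position 48
MSMDISDFYQTFFDEADELLADMEQHLLVLQPEAPDAEQLNAIFRAAHSIKGGAGTFGFSVLQETTHLME
NLLDEARRGEMQLNTDIINLFLETKDIMQEQLDAYKQSQEPDAASFDYICQALRQLALEA
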