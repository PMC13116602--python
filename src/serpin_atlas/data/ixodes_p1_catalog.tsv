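serpin_name	p1	p1_prime	reported_class
S1c1	R		coagulation_complement
S2c1	S		tissue_protection
S3c1	K		coagulation_complement
S4c1	G		tissue_protection
S5c2	N		unknown
S6c3	R		coagulation_complement
S7c3	L		inflammation_control
S8c4	R		coagulation_complement
S9c4	R		coagulation_complement
S10c5	I		inflammation_control
S11c5	K		coagulation_complement
S12c5	S		tissue_protection
S13c5	R		coagulation_complement
S14c10	N		unknown
S15c10	N		unknown
S16c10	N		unknown
S17c10	L		inflammation_control
S18c10	V	S	dual
S19c10	L		inflammation_control
S20c10	S		tissue_protection
S21c10	E		unknown
S22c10	E		unknown
S23c10	E		unknown
S24c10	E		unknown
S25c10	S		tissue_protection
S26c10	V	S	dual
S27c10	S		tissue_protection
S28c10	G		tissue_protection
S29c10	I		inflammation_control
S30c10	R		coagulation_complement
S31c10	R		coagulation_complement
S32c10	Y		inflammation_control
S33c10	Y		inflammation_control
S34c10	S		tissue_protection
S35c10	S		tissue_protection
S36c10	S		tissue_protection
S37c10	K		coagulation_complement
S38c10	A		tissue_protection
S39c10	K		coagulation_complement
S40c10	I	S	dual
S41c10	Y		inflammation_control
S42c10	G		tissue_protection
S43c10	I		inflammation_control
S44c10	G		tissue_protection
S45c10	L		inflammation_control
S46c10	K		coagulation_complement
S47c10	R		coagulation_complement
S48c10	L		inflammation_control
S49c10	R		coagulation_complement
S50c10	E		unknown
S51c10	R		coagulation_complement
S52c10	R		coagulation_complement
S53c10	R		coagulation_complement
S54c10	R		coagulation_complement
S55c10	G		tissue_protection
S56c10	G		tissue_protection
S57c10	A		tissue_protection
S58c10	R		coagulation_complement
S59c10	R		coagulation_complement
S60c10	R		coagulation_complement
S61c10	R		coagulation_complement
S62c10	S		tissue_protection
S63c11	G		tissue_protection
S64c11	R		coagulation_complement
S65c11	R		coagulation_complement
S66c11	R		coagulation_complement
S67c11	Y		inflammation_control
S68c11	A		tissue_protection
S69c13	S		tissue_protection
S70j234	N		unknown
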