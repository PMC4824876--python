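region	fwd_primer	rev_primer	ref_start	ref_end	insert_length
V4	GTGCCAGCMGCCGCGGTAA	GGACTACHVGGGTWTCTAAT	515	806	253
V1-V3	AGRGTTTGATYMTGGCTCAG	ATTACCGCGGCTGCTGG	8	534	490
V3-V5	CCTACGGGAGGCAGCAG	CCCGTCAATTCMTTTRAGT	341	927	551
V1-V5	AGRGTTTGATYMTGGCTCAG	CCCGTCAATTCMTTTRAGT	8	927	881
V1-V6	AGRGTTTGATYMTGGCTCAG	ACRACACGAGCTGACGAC	8	1078	1033
V1-V9	AGRGTTTGATYMTGGCTCAG	GGYTACCTTGTTACGACTT	8	1510	1464
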