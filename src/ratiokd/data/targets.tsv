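name	sequence	gene
Vim-T1	CTACATCGACAAGGTGCGC	Human vimentin
Vim-T2	TACCAAGACCTGCTCAATG	Human vimentin
Vim-T3	GAATGGTACAAATCCAAGT	Human vimentin
Vim-T4	ACCAACGACAAAGCCCGCG	Human vimentin
Vim-T5	GTACGTCAGCAATATGAAA	Human vimentin
Vim-T6	GATGAGATTCAGAATATGA	Human vimentin
Lmna-T1	AGCAGTCTCTGTCCTTCGA	Human lamin A/C
Lmna-T2	ACCTGCAGGAGCTCAATGA	Human lamin A/C
Lmna-T3	ACTGAGCACTGCTCTCAGT	Human lamin A/C
Lmna-T4	AGTCTGCTGAGAGGAACAG	Human lamin A/C
Lmna-T5	GCTGCGCAACAAGTCCAAT	Human lamin A/C
Lmna-T6	GCAGATCAAGCGCCAGAAT	Human lamin A/C
Lmna-T7	ACCAGGTGGAGCAGTATAA	Human lamin A/C
Lmna-T8	ATGATCCCTTGCTGACTTA	Human lamin A/C
Arp3-T1	GCAGCTGTATTAAACACAT	Mouse/Rat Arp3
Arp3-T2	ACATTGTCCTCTCTGGTGG	Mouse/Rat Arp3
Arp3-T3	GCCCAAGCCTATTGATGTA	Mouse/Rat Arp3
Arp3-T4	GCCTGAGTTCTACCAAGTA	Mouse/Rat Arp3
Arp3-T5	GGAGTCATGTCCTAAAGTT	Mouse/Rat Arp3
Arp3-T6	GCTTGGATCTAAGAAGCTA	Mouse/Rat Arp3
Ctrl1	GATTTTCGAATCCAAGGCT	Scramble control
Ctrl2	GCGAACCATTTTGTCAACC	Scramble control
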