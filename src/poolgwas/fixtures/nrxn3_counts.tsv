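# individual genotyping counts for the two NRXN3 SNPs, test and replication cohorts
snp_id	cohort	group	n_AA	n_AG	n_GG	allele_a	allele_b
rs11845632	test	case	18	87	70	A	G
rs11845632	test	control	46	124	74	A	G
rs11845632	replication	case	28	108	98	A	G
rs11845632	replication	control	48	138	85	A	G
rs2196447	test	case	27	96	52	A	G
rs2196447	test	control	25	116	103	A	G
rs2196447	replication	case	40	124	70	A	G
rs2196447	replication	control	32	129	110	A	G
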