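quantity	value
n_genes_total	1134
n_multi_gene	866
n_single_gene	268
n_families	184
n_tnl_families	38
n_nontnl_families	146
n_tnl_multi_gene	185
n_nontnl_multi_gene	681
n_paralog_events_tnl	28
n_paralog_events_nontnl	137
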