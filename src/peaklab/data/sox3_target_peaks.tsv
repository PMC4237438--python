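# SOX3 ChIP peaks near genes differentially expressed in Sox3-null neural
# progenitor cells (mm9). Coordinates are 1-based inclusive as curated and
# are converted to 0-based half-open on load. Continuation rows (additional
# peaks for the same gene) repeat the gene, fold change and RefSeq id.
gene	fold_change	refseq_id	chrom	start	end	location
Tmem163	-1.45	NM_028135	chr1	129472320	129472556	Intron
Slc44a5	1.44	NM_001081263	chr3	153836591	153836875	Intron
Fgfr3	1.65	NM_008010	chr5	34047895	34048514	Intergenic
Cpv1	1.41	NM_025817	chr6	53860009	53860356	Intron
Cpv1	1.41	NM_025817	chr6	53984529	53984835	Intergenic
Dbx1	-2.35	NM_001005232	chr7	56889725	56889913	Intron
Gpr56	1.56	NM_018882	chr8	97524576	97524923	Intron
Cspg5	1.49	NM_013884	chr9	110154883	110154975	Intron
Cspg5	1.49	NM_013884	chr9	110183673	110183904	Intergenic
Ctgf	1.45	NM_010217	chr10	24310458	24310740	Promoter
Flrt2	1.46	NM_201518	chr12	95662522	95662885	Intergenic
Ednrb	1.53	NM_007904	chr14	104243418	104243673	Promoter
Ednrb	1.53	NM_007904	chr14	104298351	104298531	Intergenic
Ednrb	1.53	NM_007904	chr14	104298536	104298789	Intergenic
Tagln3	1.54	NM_019754	chr16	45724870	45725203	Promoter
Slit1	1.87	NM_015748	chr19	41745438	41745636	Intron
Slit1	1.87	NM_015748	chr19	41773461	41773782	Intron
Slit1	1.87	NM_015748	chr19	41790683	41791049	Intron
Sox3	-4.10	NM_009237	chrX	57972960	57973254	Intergenic
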