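chrom	gene	fold_change	n_sites	pct_hyper
chr7	Lilra5	0.057094225	2	100.0000
chr3	Casq2	0.377452087	3	100.0000
chr3	Car14	0.397536108	2	100.0000
chr17	Rps10	0.476757358	2	100.0000
chr1	Rab7l1	0.499367019	4	100.0000
chr10	Igf1	0.546404576	2	100.0000
chr11	Srsf1	1.839627401	18	0.0000
chr16	Dlg1	1.843121706	19	5.2632
chr15	Rictor	1.850269418	31	9.6774
chr10	Ppa1	1.856936562	17	5.8824
chr10	Cs	1.871462757	13	0.0000
chr11	Psmd12	1.872473838	7	0.0000
chr1	Dst	1.893206535	15	0.0000
chr4	Ctnnbip1	1.901794587	20	5.0000
chr19	Smc3	1.905433481	23	4.3478
chr8	Naf1	1.915112216	13	0.0000
chr5	Limch1	1.947995552	15	0.0000
chr4	Hspg2	1.948056828	15	6.6667
chr17	Lclat1	1.980329242	15	0.0000
chr4	Sh3gl2	1.99214434	8	0.0000
chr3	Igsf3	2.016889197	22	0.0000
chr6	Aebp2	2.019027499	17	0.0000
chr7	Tshz3	2.030274352	48	4.1667
chr14	Hs6st3	2.040849538	37	0.0000
chr2	Mettl8	2.041718587	2	0.0000
chr16	Eif4g1	2.084266404	32	3.1250
chrX	Cdkl5	2.095452345	2	0.0000
chr13	Dip2c	2.110943596	11	0.0000
chr11	Ccdc88a	2.116618436	18	5.5556
chr1	Ncoa2	2.129957531	3	0.0000
chr5	Atxn2	2.171412892	35	5.7143
chr2	Tanc1	2.180687145	25	8.0000
chr4	E130308A19Rik	2.198178177	25	4.0000
chr17	Smchd1	2.209599662	3	0.0000
chr9	Pml	2.216518007	6	0.0000
chr5	Ttc28	2.221237478	13	0.0000
chr5	Lrrc8d	2.246820303	31	3.2258
chr18	Apc	2.24916978	17	0.0000
chr2	Plcb1	2.260103731	22	0.0000
chr9	Cspg4	2.272506555	4	0.0000
chr2	Rabgap1	2.290957971	12	8.3333
chr12	Srp54a	2.291532794	6	0.0000
chr17	Pgp	2.298921387	23	4.3478
chr16	Dopey2	2.345032587	17	5.8824
chr3	Fxr1	2.373885388	26	3.8462
chr12	Smoc1	2.416242757	18	5.5556
chr2	Cybrd1	2.475468964	14	0.0000
chr11	Plcd3	2.564426619	3	0.0000
chr12	Glrx5	2.611097466	26	7.6923
chr5	Ptpn12	2.64924452	4	0.0000
chr3	Sec62	2.700480763	5	0.0000
chr8	Gse1	2.747996289	36	8.3333
chr3	2810046L04Rik	2.790913895	11	0.0000
chr18	Mbp	2.791553334	2	0.0000
chr1	Cab39	2.843285092	21	0.0000
chr6	Ccnd2	2.853125022	8	0.0000
chr8	2310036O22Rik	3.340649265	14	7.1429
chr10	Ppp1r12a	3.800728332	28	3.5714
chr4	CK137956	3.848546303	4	0.0000
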