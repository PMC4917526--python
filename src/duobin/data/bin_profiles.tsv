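# Profile of the 13 dominant genome bins recovered from a two-condition (traditional
# vs accelerated withering) grape-berry surface shotgun metagenome survey.
# coverage_major is the bin's mean coverage in its dominant dataset; fold_ratio is the
# abundance ratio between the dominant and the minor dataset (ratios not reported for
# Pseudomonas/Erwinia bins are fixed at 100).
bin_id	dataset	name	lineage	n_scaffolds	total_length_bp	gc_percent	essential_found	essential_duplicated	coverage_major	fold_ratio	aa_identity	nt_identity
1	AW	Clostridium_sp_01	k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Clostridiaceae;g__Clostridium	112	4456330	30.9	105	0	2521.4	2400	81.5	66.4
2	AW	Clostridium_sp_02	k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Clostridiaceae;g__Clostridium	103	5268949	29.1	105	0	2521.4	2400	89.3	86.5
3	AW	Lactobacillales_sp_03	k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales	270	3864387	42.3	72	0	645474.2	4000	83.3	62.1
4	AW	Erwinia_billingiae_04	k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae;g__Erwinia;s__Erwinia billingiae	173	4663534	54.7	80	0	137.2	100	99.4	98.1
5	AW	Pantoea_vagans_05	k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae;g__Pantoea;s__Pantoea vagans	189	4663534	55.0	40	0	1448.1	740	99.2	97.2
6	TW	Pantoea_sp_06	k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae;g__Pantoea	172	4234112	55.4	89	0	8.6	100	93.9	87.8
7	TW	Pseudomonas_sp_07	k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales;f__Pseudomonadaceae;g__Pseudomonas	233	8444622	60.6	66	0	630.3	100	93.1	88.1
8	TW	Pseudomonas_syringae_08	k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales;f__Pseudomonadaceae;g__Pseudomonas;s__Pseudomonas syringae	177	4540557	59.2	68	0	97	100	98.6	97.1
9	TW	Pseudomonas_sp_09	k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales;f__Pseudomonadaceae;g__Pseudomonas	224	4145951	59.2	14	0	274.4	100	94.1	90.05
10	TW	Paenibacillus_sp_10	k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;f__Paenibacillaceae;g__Paenibacillus	57	5684618	40.9	68	0	5042.8	4000	81.7	86.5
11	TW	Paenibacillus_sp_11	k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;f__Paenibacillaceae;g__Paenibacillus	70	6879406	45.9	104	0	5042.8	4000	84	63.8
12	TW	Actinomycetales_sp_12	k__Bacteria;p__Actinobacteria;c__Actinobacteria;o__Actinomycetales	246	3863727	63.9	80	0	4390	3700	83.2	75.7
13	TW	Pseudomonas_sp_13	k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales;f__Pseudomonadaceae;g__Pseudomonas	96	3898344	60.4	75	0	207.9	100	92.4	89.1
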