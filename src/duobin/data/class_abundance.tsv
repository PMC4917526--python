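# Relative abundance (%) of prokaryotic classes on grape-berry surfaces after traditional
# (TW) and accelerated (AW) post-harvest withering, clade-marker profiling of shotgun reads.
lineage	TW	AW
k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria	94.0720	84.9150
k__Bacteria;p__Proteobacteria;c__Alphaproteobacteria	1.3884	0.1623
k__Bacteria;p__Bacteroidetes;c__Sphingobacteria	1.2101	4.6223
k__Bacteria;p__Proteobacteria;c__Deltaproteobacteria	1.1684	0.4152
k__Bacteria;p__Proteobacteria;c__Betaproteobacteria	1.0192	0.5203
k__Bacteria;p__Actinobacteria;c__Actinobacteria	0.7383	0.0179
k__Bacteria;p__Chlamydiae;c__Chlamydiae	0.1423	0.4725
k__Bacteria;p__Chloroflexi;c__Thermomicrobia	0.0465	0.3569
k__Bacteria;p__Firmicutes;c__Clostridia	0.0359	6.48421
k__Bacteria;p__Firmicutes;c__Bacilli	0.0349	1.29394
k__Bacteria;p__Thermi;c__Deinococci	0.0344	0.01114
k__Bacteria;p__Cyanobacteria;c__Cyanophyceae	0.0157	0.0009
k__Bacteria;p__Firmicutes;c__Negativicutes	0.0126	0.0070
k__Bacteria;p__Acidobacteria;c__Acidobacteria	0.0118	0.0128
k__Bacteria;p__Thermi;c__Thermi	0.0088	0.0000
k__Bacteria;p__Proteobacteria;c__Epsilonproteobacteria	0.0076	0.0369
k__Bacteria;p__Bacteroidetes;c__Bacteroidia	0.0061	0.0191
k__Bacteria;p__Synergistetes;c__Synergistia	0.0061	0.0000
k__Bacteria;p__Verrucomicrobia;c__Opitutae	0.0043	0.0000
k__Bacteria;p__Chloroflexi;c__Chloroflexi	0.0036	0.0000
k__Bacteria;p__Gemmatimonadetes;c__Gemmatimonadetes	0.0033	0.0000
k__Bacteria;p__Verrucomicrobia;c__Spartobacteria	0.0029	0.0000
k__Bacteria;p__Proteobacteria;c__Zetaproteobacteria	0.0028	0.0004
k__Bacteria;p__Chloroflexi;c__Anaerolineae	0.0024	0.0005
k__Bacteria;p__Cyanobacteria;c__Gloeobacteria	0.0023	0.0000
k__Bacteria;p__Acidobacteria;c__Solibacteres	0.0022	0.0000
k__Bacteria;p__Chlorobi;c__Chlorobia	0.0021	0.0000
k__Bacteria;p__Planctomycetes;c__Planctomycetacia	0.0021	0.0000
k__Bacteria;p__Lentisphaerae;c__Lentisphaerae_uncl	0.0014	0.0000
k__Bacteria;p__Chloroflexi;c__Dehalococcoidetes	0.0011	0.0000
k__Bacteria;p__Chrysiogenetes;c__Chrysiogenetes	0.0005	0.0000
k__Bacteria;p__Verrucomicrobia;c__Verrucomicrobiae	0.0003	0.0000
k__Bacteria;p__Aquificae;c__Aquificae	0.0000	0.0042
k__Bacteria;p__Bacteroidetes;c__Cytophagia	0.0000	0.0002
k__Bacteria;p__Deferribacteres;c__Deferribacteres	0.0000	0.0028
k__Bacteria;p__Dictyoglomi;c__Dictyoglomia	0.0000	0.0008
k__Bacteria;p__Firmicutes;c__Erysipelotrichi	0.0000	0.0037
k__Bacteria;p__Bacteroidetes;c__Flavobacteria	0.0000	0.0956
k__Bacteria;p__Fusobacteria;c__Fusobacteria	0.0000	0.2326
k__Bacteria;p__Tenericutes;c__Mollicutes	0.0000	0.1460
k__Bacteria;p__Nitrospirae;c__Nitrospira	0.0000	0.0009
k__Bacteria;p__Spirochaetes;c__Spirochaetes	0.0000	0.0257
k__Bacteria;p__Thermotogae;c__Thermotogae	0.0000	0.0101
k__Bacteria;p__WWE1;c__WWE1_uncl	0.0000	0.0001
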