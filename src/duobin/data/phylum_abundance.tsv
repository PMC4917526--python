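# Relative abundance (%) of prokaryotic phyla on grape-berry surfaces after traditional
# (TW) and accelerated (AW) post-harvest withering, clade-marker profiling of shotgun reads.
lineage	TW	AW
k__Bacteria;p__Proteobacteria	97.6583	86.0501
k__Bacteria;p__Bacteroidetes	1.2162	4.7371
k__Bacteria;p__Actinobacteria	0.7383	0.0179
k__Bacteria;p__Chlamydiae	0.1423	0.4725
k__Bacteria;p__Firmicutes	0.0833	7.7888
k__Bacteria;p__Chloroflexi	0.0536	0.3574
k__Bacteria;p__Thermi	0.0431	0.0111
k__Bacteria;p__Cyanobacteria	0.0180	0.0009
k__Bacteria;p__Acidobacteria	0.0140	0.0128
k__Bacteria;p__Verrucomicrobia	0.0075	0.0000
k__Bacteria;p__Synergistetes	0.0061	0.0000
k__Bacteria;p__Gemmatimonadetes	0.0033	0.0000
k__Bacteria;p__Chlorobi	0.0021	0.0000
k__Bacteria;p__Planctomycetes	0.0021	0.0000
k__Bacteria;p__Lentisphaerae	0.0014	0.0000
k__Bacteria;p__Chrysiogenetes	0.0005	0.0000
k__Bacteria;p__Aquificae	0.0000	0.0042
k__Bacteria;p__Deferribacteres	0.0000	0.0028
k__Bacteria;p__Dictyoglomi	0.0000	0.0008
k__Bacteria;p__Fusobacteria	0.0000	0.2326
k__Bacteria;p__Nitrospirae	0.0000	0.0009
k__Bacteria;p__Spirochaetes	0.0000	0.0257
k__Bacteria;p__Tenericutes	0.0000	0.1460
k__Bacteria;p__Thermotogae	0.0000	0.0101
k__Bacteria;p__WWE1	0.0000	0.0001
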