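# NCBI Taxonomy snapshot (accession, label, prefix) — common study organisms
NCBITaxon:9606	Homo sapiens	NCBITaxon
NCBITaxon:10090	Mus musculus	NCBITaxon
NCBITaxon:10116	Rattus norvegicus	NCBITaxon
NCBITaxon:4932	Saccharomyces cerevisiae	NCBITaxon
NCBITaxon:7227	Drosophila melanogaster	NCBITaxon
NCBITaxon:6239	Caenorhabditis elegans	NCBITaxon
NCBITaxon:3702	Arabidopsis thaliana	NCBITaxon
NCBITaxon:562	Escherichia coli	NCBITaxon
NCBITaxon:7955	Danio rerio	NCBITaxon
NCBITaxon:9913	Bos taurus	NCBITaxon
NCBITaxon:9823	Sus scrofa	NCBITaxon
NCBITaxon:9031	Gallus gallus	NCBITaxon
NCBITaxon:8355	Xenopus laevis	NCBITaxon
NCBITaxon:9986	Oryctolagus cuniculus	NCBITaxon
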