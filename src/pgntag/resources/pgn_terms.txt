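# protein/gene names consulted by the error-categorization cascade
Ras
c-fos
Wnt
p53
Src
Myc
E-cadherin
beta-catenin
glucocorticoid receptor
insulin receptor
epidermal growth factor receptor
TP53
BRCA1
IL-2
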