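# biomedical vocabulary that is specific to the literature but not a
# protein/gene name
polymerase
olymerase
prion
IgM
IgG
cytokine
chemokine
ligand
kinases
proteasome
ribosome
interleukin
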