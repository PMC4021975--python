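# frequent general-English words that dictionary taggers wrongly mark
plasma
renal
inhibitor
antibodies
antibody
blood
liver
membrane
activity
expression
binding
factor
region
complex
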