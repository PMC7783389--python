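target
targets
gene
genes
protein
proteins
enzyme
enzymes
receptor
receptors
kinase
kinases
expression
expressed
encoding
encoded
transcription
phosphorylation
mutation
mutations
overexpression
knockdown
signaling
pathway
domain
subunit
isoform
polymerase
transcriptase
inhibitor
inhibitors
binding
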