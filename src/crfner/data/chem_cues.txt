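inhibit
inhibits
inhibited
inhibition
inhibitor
inhibitors
chemical
chemicals
compound
compounds
drug
drugs
molecule
molecules
agent
agents
dose
doses
analog
analogs
derivative
derivatives
ligand
ligands
substrate
substrates
agonist
antagonist
treatment
administration
synthesis
synthesized
potency
ic50
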