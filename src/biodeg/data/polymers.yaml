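# Built-in polymer repeat-unit registry (cellulose as anhydroglucose monomer)
PE: C2H4
PET: C10H8O4
PCL: C6H10O2
cellulose: C6H10O5
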