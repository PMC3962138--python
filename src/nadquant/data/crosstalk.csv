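source,target,mechanism,fraction
NR,Nam,on_source_fragmentation,0.2
NMN,Nam,on_source_fragmentation,0.2
NAR,NA,on_source_fragmentation,0.2
NAMN,NA,on_source_fragmentation,0.2
Cytidine,Uridine,isotopologue_bleed,0.10
Nam,NA,isotopologue_bleed,0.07
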