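metabolite,standard_set,precursor_offset_da,fragment_offset_da
Cytidine,C13_extract,5,0
Uridine,C13_extract,5,0
NR,C13_extract,5,0
NAR,C13_extract,5,0
Inosine,C13_extract,5,0
CMP,C13_extract,5,0
UMP,C13_extract,5,0
NMN,C13_extract,5,0
NAMN,C13_extract,5,0
IMP,C13_extract,5,0
ADP,C13_extract,5,0
ATP,C13_extract,5,5
ADPr,C13_extract,10,5
NAD,C13_extract,10,5
NAAD,C13_extract,10,5
NADH,C13_extract,10,10
NADP,C13_extract,10,10
NADPH,C13_extract,10,10
Nam,O18_vitamins,2,2
NR,O18_vitamins,2,2
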