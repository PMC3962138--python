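name,precursor_mz,fragment_mz,collision_energy,cone_voltage,rt_min,separation,quantifiable,notes
Nam,123,96,16,32,9.82,acidic,true,
NA,124,53,26,32,8.35,acidic,true,quantified via heavy-Nam correction factor
Cytidine,244,112,18,18,11.14,alkaline,true,
Uridine,245,113,16,18,11.50,alkaline,true,channel receives isotopologue bleed from cytidine
NR,255,123,12,14,8.98,acidic,true,
NAR,256,124,13,14,10.33,alkaline,true,
Inosine,269,137,12,12,12.88,alkaline,true,
CMP,324,112,22,16,2.97,alkaline,true,
UMP,325,97,12,20,4.11,alkaline,true,
NMN,335,123,12,16,8.92,alkaline,true,
NAMN,336,124,12,18,4.20,alkaline,true,
IMP,349,137,22,14,9.65,alkaline,true,quantified via NMN correction factor
ADP,428,136,26,30,10.43,alkaline,true,
ATP,508,410,16,30,10.51,alkaline,true,
ADPr,560,348,16,26,11.08,alkaline,true,
NAD,664,428,26,26,13.64,alkaline,true,
NAAD,665,428,24,24,11.89,alkaline,true,
NADH,666,649,20,26,12.98,alkaline,true,
NADP,744,604,18,26,12.01,alkaline,true,interpret with care; may include oxidized NADPH
NADPH,745,729,48,28,12.10,alkaline,false,not reliably quantifiable; nominal RT placeholder
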