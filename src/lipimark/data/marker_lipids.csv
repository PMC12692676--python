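name,formula,molecular_weight,ionization,category
Carnitine C16:0,C23H45NO4,399.33,[M+H]+,Fatty Acyls
Carnitine C17:0,C24H47NO4,413.35,[M+H]+,Fatty Acyls
Carnitine C18:0,C25H49NO4,427.37,[M+H]+,Fatty Acyls
Carnitine C3:0,C10H19NO4,217.13,[M+H]+,Fatty Acyls
Carnitine C5:1,C12H21NO4,243.15,[M+H]+,Fatty Acyls
PC (16:0_16:1),C40H78NO8P,731.55,[M+COOH]-,Glycerophospholipids
PC (18:1_24:1),C50H96NO8P,869.69,[M+COOH]-,Glycerophospholipids
PG (16:0_20:0),C42H83O10P,778.57,[M-H]-,Glycerophospholipids
PI (18:0_18:1),C45H85O13P,864.57,[M-H]-,Glycerophospholipids
PS (18:0_16:1),C40H76NO10P,761.52,[M-H]-,Glycerophospholipids
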