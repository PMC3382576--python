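stage,start_ma,end_ma
Tithonian,150.8,145.5
Berriasian,145.5,140.2
Valanginian,140.2,136.4
Hauterivian,136.4,130.0
Barremian,130.0,125.0
Aptian,125.0,112.0
Albian,112.0,99.6
Cenomanian,99.6,93.5
Turonian,93.5,89.3
Coniacian,89.3,85.8
Santonian,85.8,83.5
Campanian,83.5,70.6
Maastrichtian,70.6,65.5
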