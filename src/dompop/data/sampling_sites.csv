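population,site,valley,longitude,latitude,altitude_m,n_sampled
YMF,"Yangmao Flat, Lanxin Town, Mao County",Minjiang River,103°44′17″E,31°35′12″N,,20
FHB,"Feihong Bridge, Mao County",Minjiang River,103°45′31″E,31°48′26″N,2200,23
SDG,"Shida Gate, Mao County",Minjiang River,103°43′10″E,31°52′22″N,1770,20
SEG,"Seergu, Heishui County",Heishui River,103°25′5″E,31°54′47″N,1820,23
XV,"Xue Village, Li County",Zagunao River,103°20′47″E,31°32′26″N,1630,23
TF,"Tao Flat, Li County",Zagunao River,103°29′47″E,31°35′29″N,1500,21
WZT,"Weizhou Town, Wenchuan County",Zagunao River,103°37′45″E,31°30′35″N,1700,19
SP,"Sha Pit, Wenchuan County",Minjiang River,103°36′32″E,31°28′43″N,1600,23
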