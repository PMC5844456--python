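code,name,compound_class,ri,molecular_ion,diagnostic_ions
BQ,"1,4-benzoquinone",benzoquinone,917,108,82;80;54
NQ,"1,4-naphthoquinone",naphthoquinone,1422,158,130;104;102;76;75
ND,"1,4-naphthalenediol",naphthalenediol,1493,160,132;131;105;104;77;76
MNQ,"6-methyl-1,4-naphthoquinone",naphthoquinone,1547,172,157;144;118;116;115;90;89
CNQ,"4-chloro-1,2-naphthoquinone",chloro-naphthoquinone,1604,192,164;157;129;104;101;76;75;74
MOQ,"2-methoxy-1,4-naphthoquinone",naphthoquinone,1782,188,173;160;159;158;131;130;104;102;101;89;76
MMOQ,"methoxy-methyl-1,4-naphthoquinone",naphthoquinone,1911,202,187;174;173;172;146;145;144;131;118;116;115;103;89;77
MAQ,"2-methyl-9,10-anthraquinone",anthraquinone,2134,222,221;207;194;193;166;165;164;163;139
DMAQ,"1,2-dimethyl-9,10-anthraquinone",anthraquinone,2277,236,235;221;208;207;193;179;178;165
ABQ,"alkyl-substituted 1,4-benzoquinones",alkyl-benzoquinone,,,
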