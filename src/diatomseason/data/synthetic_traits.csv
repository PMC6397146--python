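taxon,sensitivity,indicator_weight,guild
AMIN,1.5,2,low_profile
APED,4.0,2,low_profile
GPAR,4.5,2,high_profile
NLAN,3.5,2,motile
GOLI,2.5,1,high_profile
MCIR,2.0,1,low_profile
RABB,2.5,2,low_profile
EMIN,2.0,1,high_profile
SCRU,3.0,1,motile
CEUG,3.5,2,low_profile
NCRY,3.0,2,motile
CBAC,3.5,1,motile
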