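site_label,protein_isoform,dephos_peptide,phos_peptide,charges_used,flyability_k
α1-S347,α1,DFYLATSPPDSFLDDHHLTRPHPER,DFYLATS[+80]PPDSFLDDHHLTRPHPER,4,0.58
α1-S477,α1,SGTATPQR,S[+80]GTATPQR,2,1.30
α1-T481,α1,SGTATPQR,SGTAT[+80]PQR,2,1.11
α1-S487,α1,SGSVSNYR,SGS[+80]VSNYR,1;2,1.10
α1-S499,α1,SDSDAEAQGK,SDS[+80]DAEAQGK,1;2,0.98
α2-S345,α2,IMNQASEFYLASSPPSGSFMDDSAMHIPPGLKPHPER,IMNQASEFYLASS[+80]PPSGSFMDDSAMHIPPGLKPHPER,5,0.83
α2-S377,α2,MPPLIADSPK,MPPLIADS[+80]PK,1;2,0.89
α2-S481,α2,SGSSTPQR,S[+80]GSSTPQR,1;2,1.35
α2-T485,α2,SGSSTPQR,SGSST[+80]PQR,1;2,1.18
α2-S501,α2,SSFDSTTAESHSLSGSLTGSLTGSTLSSVSPR,SS[+80]FDSTTAESHSLSGSLTGSLTGSTLSSVSPR,3;4,1.56
β1-S182,β1,C[−1]SDVSELSSSPPGPYHQEPYVC[−1]KPEER,C[−1]SDVSELSSS[+80]PPGPYHQEPYVC[−1]KPEER,3;4,1.31
β2-S108,β2,SHNDFVAILDLPEGEHQYK,S[+80]HNDFVAILDLPEGEHQYK,3;4,2.97
β2-S184,β2,DLSSSPPGPYGQEMYAFR,DLSSS[+80]PPGPYGQEMYAFR,3,1.02
γ2-S113,γ2,TVFPFSYQESPPR,TVFPFSYQES[+80]PPR,2;3,5.11
γ2-S143,γ2,ESSPNSNPATSPGGIR,ESSPNSNPATS[+80]PGGIR,2;3,1.87
γ2-S162,γ2,TSGLSSSPSTPTQVTK,TSGLSSS[+80]PSTPTQVTK,2;3,2.79
γ2-S196,γ2,IYASSSPPDTGQR,IYASSS[+80]PPDTGQR,2;3;4,0.71
γ3-S14,γ3,TPSWSSLGGSEHQEMSFLEQENSSSWPSPAVTSSSER,TPS[+80]WSSLGGSEHQEMSFLEQENSSSWPSPAVTSSSER,3;4,0.99
γ3-S65,γ3,SVEEGEPPGQGEGPR,S[+80]VEEGEPPGQGEGPR,2,12.22
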