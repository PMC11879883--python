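"""Published precursor m/z of the 19-site AMPK cognate peptide panel.

One entry per unique (species, dominant charge): the dephospho peptides
shared by positional isomers appear once.  Values as printed, 4 d.p.
"""

TABLE2_MZ = [
    # dephospho peptides
    ("DFYLATSPPDSFLDDHHLTRPHPER", 4, 741.6072),
    ("SGTATPQR", 2, 409.2118),
    ("SGSVSNYR", 2, 435.2092),
    ("SDSDAEAQGK", 2, 504.2174),
    ("IMNQASEFYLASSPPSGSFMDDSAMHIPPGLKPHPER", 5, 809.1845),
    ("MPPLIADSPK", 2, 534.7915),
    ("SGSSTPQR", 2, 410.2014),
    ("SSFDSTTAESHSLSGSLTGSLTGSTLSSVSPR", 3, 1048.5040),
    ("C[−1]SDVSELSSSPPGPYHQEPYVC[−1]KPEER", 4, 755.3366),
    ("SHNDFVAILDLPEGEHQYK", 4, 553.7722),
    ("DLSSSPPGPYGQEMYAFR", 3, 667.9719),
    ("TVFPFSYQESPPR", 2, 777.8830),
    ("ESSPNSNPATSPGGIR", 2, 785.8764),
    ("TSGLSSSPSTPTQVTK", 2, 789.4045),
    ("IYASSSPPDTGQR", 2, 689.8335),
    ("TPSWSSLGGSEHQEMSFLEQENSSSWPSPAVTSSSER", 4, 1007.1987),
    ("SVEEGEPPGQGEGPR", 2, 762.8499),
    # mono-phosphopeptides
    ("DFYLATS[+80]PPDSFLDDHHLTRPHPER", 4, 761.5988),
    ("S[+80]GTATPQR", 2, 449.1949),
    ("SGTAT[+80]PQR", 2, 449.1949),
    ("SGS[+80]VSNYR", 2, 475.1924),
    ("SDS[+80]DAEAQGK", 2, 544.2006),
    ("IMNQASEFYLASS[+80]PPSGSFMDDSAMHIPPGLKPHPER", 5, 825.1777),
    ("MPPLIADS[+80]PK", 2, 574.7747),
    ("S[+80]GSSTPQR", 2, 450.1846),
    ("SGSST[+80]PQR", 2, 450.1846),
    ("SS[+80]FDSTTAESHSLSGSLTGSLTGSTLSSVSPR", 3, 1075.1595),
    ("C[−1]SDVSELSSS[+80]PPGPYHQEPYVC[−1]KPEER", 4, 775.3281),
    ("S[+80]HNDFVAILDLPEGEHQYK", 4, 573.7638),
    ("DLSSS[+80]PPGPYGQEMYAFR", 3, 694.6273),
    ("TVFPFSYQES[+80]PPR", 2, 817.8662),
    ("ESSPNSNPATS[+80]PGGIR", 2, 825.8596),
    ("TSGLSSS[+80]PSTPTQVTK", 2, 829.3877),
    ("IYASSS[+80]PPDTGQR", 2, 729.8167),
    ("TPS[+80]WSSLGGSEHQEMSFLEQENSSSWPSPAVTSSSER", 4, 1027.1903),
    ("S[+80]VEEGEPPGQGEGPR", 2, 802.8330),
]
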