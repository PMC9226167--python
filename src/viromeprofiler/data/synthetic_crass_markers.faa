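>crass_terminase synthetic stand-in marker (random sequence)
MDHCRIENRMYENHGWSYPLVIFFQWAHQWCRLIHDDIREFFDNTIAWYPISNRCDEWRR
NGADDQNQVRGNMWQHIPHMQNGNETICMMMHWFERDVFQEVYANWSIMEILVLEWGEEL
CDHAQKHLDYVGLMMWTMDMGVHWCNFHQILGQSIGMKHTPDDMYQDRGTIPPEFPYSSV
DMLCASHMFSYSGRNGCCCSMATISYFVLQEESYQPYPKSCEFPKTAAQISKSLRCTGTV
LASGQERGESVIKNEVQYLCRFWWAMTKMVCTFFMQTWDDYTTCERRGGIFKWSWVVNMR
FYIFEVGYWKVYDCDQLQMFSPMFWCGKQLHMGTYHNDLYGWVACDCGDIEAWKVVDSIE
GHYPRFCQFGGPNWSHKNCIIIYLGVTAADMPDRSIVSLGPSYDQKMDTCGGLIRCMLWN
EYKLYRCYNMQQQMCNPIHWCFLMWLQCYNPHERQLFYRCSFYCSVETMSSQRFVGKATW
TDLGQDSLRPNVPKPGLRHAINPLQVKFCFDWPQCEMENS
>crass_polymerase synthetic stand-in marker (random sequence)
PQSGCPTPMFKHIVSHRMPTLKSYLCPWQFQLVRKTVDTDIARASQKRCTYGPAYTQEDI
QWHVLPQENFKIFWGDDLANVRAMHSKMVGLVGGFCVNIGCLAYAPVLYMGKHDIIQYNT
YWTRPIPIKHHHAELLAGAKQGDKLMLEAFWTRSHHETEVCKPYFIIWHKDDGGKSEARS
ATDHTTAIYAVNNIKAGAAHSTLTKQCWLMFTIEIRMLPEEGYRQVPAAICIHPHKSAHA
NNPTHKFHVGGHHDQEAFFNLFKFVFEKHTNDCARRTQNRTMNYFLAILLDQEFEHYWVG
HNYVTTPFPDGKYVYGYITQPHYMSEFNNMDCMMQTVEQDRFSVTLQVFNNGVPLQDCVY
RVGDTTRSPKTPTSGWQEFFDLTGHTACEYCYYPEFYMGNGLGCKFSPSQAEERTFLAKK
LTTGPSDYFAHMPVVKIAHIAEKHQNRAMESDPDLVYMYVAYLIVCPYPSFFKWKQQTYH
DWFAKLFPKDYLYHKHFCTHPKPNMGCKQVYYVNKNSPEGRYPPPVTYDPNHVHGLCHMA
AEQATLCLELRYWVDCHMKQWRYLKCYHIPAWDGKIEDDIWSKRADSATSHRPPTGRHQC
KYMRILLDDNKPYAYRVACLYQTGSCWCNSYDGLGQQNVI
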