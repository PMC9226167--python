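>terminase_large_subunit synthetic stand-in marker (random sequence)
NKLISHSHIELIMQQRRTQNQGAYNVMFNRSDEETLFAEERSCKMMPLETTESLDVLSML
DVMICHNQCTYHPWAIRSGNWEKLEFPWFRFPYEAKLHWDRVKDLPNYHTCNWSEPWEVA
RPKLMHGMIPFAQNFDIIHNISMHGISVYNWFKWRRTEHPTFVHKELYYMIWELCINDPQ
TTWNHRDTHNGYHNWNCIHTRVTSCNANHSWPIGLVEYMCENQKFNGNQFRQNPQQYSPH
HCAKTPGEMIHPCWRREPSSHDMECNHKWIYDSHWHYMTSFWWSWGTYNSNCFTGNSLHD
VEFWEYIRHMWFTKYAHKMCGTHNYVLCWYIKSEKMIMTIQMAVRDNNPQWGQCPEEWFW
QIAMCQLLWMHMMWCWHFQPFAMHKCGDPQVYDTFEMTYRKAYVTQLVMWIQRPNGQLTS
AWTMKSGAACCHVESRPFNNWQVMSKIWLTHQKWPICDDW
>portal_protein synthetic stand-in marker (random sequence)
YWEWRKNWNWLHAYFETRMHALFASQVNMAGRSNLKKDPSNNFGQMSQLNEFRTGRIIIE
GTINFNQPCFYESRWSGQHHKLDWALCIISNSVTFTEISMIRTANMHWYMYVEQSMSQIE
HAHSKWVEMALNGTEMASSRVIWWVPANSNINWDMLICYEGILPLFHWWNSDNASCFHCN
NWFAIYRACGCDLRLESWFMHVKAPRVVITFLNIQQMQSNFFMWVKFFIVQANKNNVTPI
WWICVGDYTCFTFDPFPTQTPLINSPTNHHIMHYMEHNIFQVDFIIDGCPCSPVQHNCDQ
VSRIHLDWNIQEAAMKLFMRWVLTYVSVPVWDIKFWVVKKENRPAHEEPDNTDNWETHTR
RFVRIQIPLYRNVILMSASWETRRNTWLNQDTGCIKRTKEYGYKILGQLIRGEVQDQVYA
>clp_protease synthetic stand-in marker (random sequence)
TNYKMNRRAPIRDFDSRYKQTSPEWYMMEWPNAQKPQLFECWIVFHCYNTNSEPWSWQST
DPIWIHPPQNNYQCMWIHDKHHVRWALMPLPPHNNKGTSDPNNCCCEDQWAGWAWDHREH
YNLLGHLYTGVYCFLRNRDARCRNPGMGNEWREYVYCWGKSSRKTISSLIQLTSTGMPPG
VWPARNIRKPWDWNKEDTFYDMSIQTIDHGWVTSECMYNAHSHLYLCWSW
>major_capsid_protein synthetic stand-in marker (random sequence)
RAFIANMTYSVPWWLEHFYDYAWTRMCTHNNEDNILQARMSNMMKCIDTGNLAIHINMHF
VPQCQPQKFDKSVAHPKLQQIAAHKFCLKLGELMWFNFTVEECDLAPCISDERACMYPFG
AYNPPMSTKHQKIRKHWWESKHAVFHLWVLTALVGSEEHLHTMWTEAEKSKDISVFKGYK
IYYLQYNVACPVDCVSTAWGCEIEAAENQEHCMFSGQTDVCQRLRHTMLMAHRLEDCFHS
PGSDQLQEIGEYMNAPWIQCKVIIHYHGPHNLPLIMKHAMRDTIRNFLSSEVMMYWNYNT
YSNLENMQSGQDMHGVQNLFSETQNAQMVVICMAHYSPRAPDWNEELGRL
>dna_polymerase_I synthetic stand-in marker (random sequence)
EQVQQIIFDCNWVSENPIDVWVRPHTPCYLFEGNFPFSFVHQSGVNSANPCNFFYQNSFH
KPYHTMPTHPYGSRHDSPPQYQIQKAQFPTSVYIFWAIIWDKFETRCVRCVTMGIIPKHP
EIHFWCNHARDWSEHQLGKHTPNNSLWCHMAWHPTTQVHLWDCSMYRIMFVSDTRVTHLM
DDNRVEFNTRQLDWVCTKAYKQPNNCSWWCWMYPDVVIDMKQHRCAIHVRNRSTHYILWI
ADYQKYQHQMSQGMANDAYAKQPGNWPGEQWKWPNYKCPYPAWWLFSPDNGRIMHSDIKA
PCHDRLEPDECADDGMGLRDNDAMVEMDTEKGALHTIMTINRQHYGVWNCCQKKSEWDRR
YIMDLNAKLNQRVSMRVMEDAKMGVPVPRPCPVQQMMHDNQNKVVKKQMYLTIKDERFWT
LRKAWKQCGPVGDVSSTSQGMDYKATWVDWTAPRPCQPSFENGFAPVSGVLGTRRSIRSV
DTWYIKKYLWHPNHGHRKGVMGHFNYWFHWDRMCRYWDQRRQRIMPRWKYIWGISNFMEN
KTRFLTNSKT
>snf2_helicase synthetic stand-in marker (random sequence)
SQRIYIQESFAFRKYMRWDCGHGKSRKEHQTDNSLRDDVRQLWMNPWVSDAHITYDELAH
RGEDYCGKKVCNKVFCVRPGRTCFAYESSSPGPVALRITGTIFEIWARPAYRGEHPMVDT
CYCASIMKQHSVYALGFSKKLGDMIWYQAEMDVQGAAKQQNKMILFRSPYIPDDISWDTM
MCRAVHHFHGEFIFLCGCTWCCPLANTILMNGLYYPNHQGVIGCHHNSGQYQAEPKVNMA
DYCFNRPYWMHFVHFDARWYTAPFLLTPQVEVHFCIQVFAIKPTQVPHNEQRGDKFDEEE
FMQEMALACNSIIDGKEQNYMHNRSTAQHGRMKWDAGHTRREVSARKNEWCYNSTVSQPF
FGNPTCSWKKFDPLDWDKNVQCCPYIFRSLLSLCSSTVISVLYWRWEKTLRKIAISIEYD
SGAFMTQAACICEDYTEFENFAHGQITPHWMFCGYGMHNPTPQFGKNIDRWAIAPRWRNW
WRHLEIRWQLWDFQTICAPV
>vrr_nuc_nuclease synthetic stand-in marker (random sequence)
MYHLGFHCVTDEFVCWDAICHSTIVTKVTKVGFKYNCVEWNWCPLRCYECHGKRMKWCAN
PADNMYCQRSRAAIMNMIDFAFCKDIIWWTDTLDYEHLILGVHKANQGYNFNDFCAKGEA
AFEIDDDISCWWPECVFHCLKYWESENTPLMSKMKPFKQWPKDNVSVSTVYRAVHSGEYV
YNDEHHRMYTEQCCANDWASKSPCEQQISHNHHSEMSNSVMMLQDSGFCVSANSGMHHGK
YHTATMGDIDYTTHMMCARIGTLFLVSPQCSEMNQACAWWLQFAFMCTEFAEEDHRFNDY
>duf_a synthetic stand-in marker (random sequence)
TELFKIHEKVVVELIYPWAHMKIPRATMVRQPIVGQFAAAYAKRNFGAEWKGWFLGLDIP
HIYEAAWRWRMVWDVYCAMRPSGWSMIWEAQMCWHYGFLPAFWCSFENFPCNAQQKEKYP
PVELIPYFPNQVGCHPRWMIGQGVPDWLMYDKGYWKCIADCKQRWYIHVIWNNSQHWEGK
MQDVPRKALERIRMSLFEKRCDHIPCVDWL
>duf_b synthetic stand-in marker (random sequence)
HQQINGFVHEVNGQFNLIYGQDYSFPWGTMPRWRWEFHAMQAAPYPPTGYLFQFMAKNDP
PPQCSQRPKIELMPYCPGCFFRMYVNQMNPFHMVCQMLFCVSCMFVCKMRWDQNWQLRYY
QFRYQTGSWWPYLLALKHLQTETDTKRPVGFMYIFHAVQPIMTFICMYWDKEQFVVIWMF
CTEDTMCMKGHGTTNQAQAVCIVGPAAWVGVLIPLWYRCITRQHFEVDTKHIQGYPDRKL
EYPQRDYYMMVREERNSFNM
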