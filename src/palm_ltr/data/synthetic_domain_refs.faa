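>Copia_GAG|GAG|Copia|-
QWKHFACTNFMGDSHWTKDWYSDCWSMHFWHMCTAVHDIIMKPEWAKHGRKRLAKCEQNC
EICLANVFHCNRAYQEFQIFKHKFWCYNVYKIEHHITPWVVDWFEKDNYTSDLLVFCTHG
QHRNHIAMDISNLYDNKWWRFIWNYYCVIY
>Copia_PR|PR|Copia|-
QMCDTWLAFVYNVPAINSEQEGISHMDICPLTKQKKLMAQAICQQKFRFYWPFTMVTNNQ
TCDYVNFAEEKNFMYHCVMFAEWQMIQTWRMGYCHYCELY
>Copia_INT|INT|Copia|-
YNAHKISIRWTARQLRSYKFPWEIDQYTCEEILSGGHMPMNLWEGTCHCGECKPEVFFVM
WVKIAVYEWPPGHVNFANQGTVIAQWRAQLKIHRLESNFGEHPAVRHTYHDTVDEDPKGN
EEEFFHCHPWSERLDPGEETKKCETRAYWGFYYFTNFLADGFMYLQLHPMQGPPWKDPKE
CFLEDVAYQDSPLGMWILSGQPHNCEVDFQHRGWLYRVYQVARNILWHEVFQIHWKNQHD
LYEQELDRPF
>Copia_RH|RH|Copia|-
YWQMYNHRYKACRQAFHKPVKEQKSEYNSIKWFMACKRCNMGFTWMAEAEWQANTCEKSC
WVPQHLDREEWQQGMSRESMCNCQEGCNDDFIRFQEKECWSGWKQIYTGTLMWPHALCKY
WLCQQSFILHHTMWPGKFVQMGHYTFVRNV
>Copia_Oryco_RT|RT|Copia|Oryco
KVLIPHQVPDEMNTSQIRRGHFACTMMYDQTIANILLLEINVNDQNEASFWHGVWPWFVW
NLKWRINSHFKFETRIKGALMQFSDTYTHVDRKMPIMRMCCPQKQPQPSGYDKTTQPISH
AHNFTMMSTHDMHKPCEMTYDEYLRQQSSNHRRILQLKDKHYDATDRWPVGVLHTHYCCG
IFKQNGGQWYNYWKKECNNLITQYTILGDMYQFRFDKNDV
>Copia_Sire_RT|RT|Copia|Sire
KIKYWSQVKDIVNASEFRRPMSQKCMMYDQGIDEIDWLSNVVCDQYCAMLWYGVLPWFEW
VLKMRIAFHFKFETRIKFSGQQFCWTYRHVDIKMSISQMCCPHVQHYPAGYPKTIQPITL
AHNFTMQKTDREHKAKEMTYTDTRMQQFTNNRRKTKLVDKSWDATKRWPVGVSHTHYCCG
IAMQNGGSWVWYWKKSCNNLKSQCWILDQKMQFMFGKQYC
>Copia_Retrofit_RT|RT|Copia|Retrofit
KVGICLQLKWIVYASGDRIGFMICVMQLDQGIAEIVHLSAPVCDRNNAMLWHGSPPWLEW
ALKMEINNHFAFENRIKFLRQVFCDTYDWVDIKMPISQHCCPKKQYDPSGYDKTTYPKTH
LHNWTMDSTVREHKPKETTYDETRYQQFTLHDRKLHLKDKSFDATTRWGVGVLHTCYCCG
IFKQNGGIWMHYSKKSTNNLITCLWILDKCYQYRWCKNYV
>Copia_Tork_RT|RT|Copia|Tork
KVLPCLQVASIVNNSGDVRGFFVPCHMYGQGIAEELLFSNVVCDQNNPMLWHSVEPWFEW
ALVMRINSHFKFETRIKCGRGQFCDTYPHVDVKMPISQVCCPAKIHLMFGSPHTTQPITH
ACNFTMQPTMMEWSPKEMTYDDNRYAQSQVHRRKLLLKDKMWDATKAWLVGVLHTFYGCF
IFKQNGGAWDHYWKKSCNNLITVPWILDTSYQFRFGKNYV
>Gypsy_GAG|GAG|Gypsy|-
NMSQSQKVARYGVYCAWKCTPLNCAKEQYLSQSWTAFMKFPLAYFNACQYQDVQVRVRYC
WCRIISKQQVRPQTFESVMTEVPCEYQNRQIGNFGSLARCAVWFERAKHVFLPWIHKDGR
CSWKWRRKISMHVVAYAHEVLAVVKIRQNY
>Gypsy_PR|PR|Gypsy|-
FYPGEQSSEQTINFMCTAPTRTMRRFPDSVIEFYRRFTSIRFKFVLMASWSDYYWPQRQN
SVGIYSFVQWSWMAAVLPKCSWILMHEHQQQHVQTQRHDC
>Gypsy_INT|INT|Gypsy|-
PCYDCMWWKEIWGNIQCIFDDVHEQSPWERFGTLRIREGPCSPNFTMCSVHGSYTMEQGP
SSKHTSEAWDETAVEMNWPIILKSCRAAYIDRKYKWMDLHTATDKNKEGCKSRHWLCPFR
DRCEECWMTIQVEQCAFNCFGEWDFHNLMLFHRMNSCWYYCCKIKQSKEDHNVMMICIHY
AKDMPRGDKFDLLHDACVPVTKASGLSGRMIWYKACLKWSPDNEWHGTTIVERFDVTMKR
IPRTQAIWLF
>Gypsy_RH|RH|Gypsy|-
TDEMEDEIMVWSTDSFITFDHASQQNLHCSPPFTNPQHCSWVRFACFMWAGREAFSHHDG
VGMDDPRFCEIDEFQPNQDIRGEEFTTTSLVCCMKAMGPCQSYRDMEVHQAFTCHKDQHN
RESEPEVSKREIGCPTIKVHNWQYKHSRLV
>Gypsy_Athila_RT|RT|Gypsy|Athila
SHMDDRTMCCYVANSQHKHRDRMTGQWGFCFDRLSRRKTEASKERSWYEVNVFFHYVGGQ
MTRQLQILVNQMKQDKWCRSEWGRLCHQLRMQSGYDWPEKPERRSWKHEGTYIISGGLWR
QLQINFIMWNWHIQINCMVMCSMEYDLANYPVSTIKFCYIGATHAFLGNMQHIRFTEAAA
HGSTQGYGVDNHWRGLERRIWHFQHAWCVELLHRYVDARQ
>Gypsy_Tat_RT|RT|Gypsy|Tat
CHMDDRIYCSDVQWSMAHTRDHMSRGWGFCFDRLSIRKTKASPYRDWWGCMVFFTYEPGL
YWWFITQDTWQMSHDKWQYSDMGRPYHQIRVCSGCIVPCFWEKRSLHPEGTYKQEAGGWM
MQGIFPYMENWHIINDCMVACTMGDDLANFPASTKKECYIGNTRWSKGNQQHYMHWEMYA
HGSTTTYPEINHWFYDLRYSKHFQDWWRVVELDQYVCYRR
>Gypsy_CRM_RT|RT|Gypsy|CRM
SHDDDRTMICYVQFSYHLTRDRMRRQWGFCHDRLPRRKTEANKNRDWWGDNVFFTYWGDT
KFVQGCQDDWQMKHRKHQRMDMGRPCVQIRCPRGVESPFKNEKLSGKEAGSYQISGNLLI
QLGIAFIMENIHIQNACMVMCTMDGDLAEYPVKTEKFCYGGVTMAFLGNHQHYRFTEAYP
AGSTQTYPVINWWRGDEYCIPHFSHWWCVDLLHRYVCYRQ
>Gypsy_Del_RT|RT|Gypsy|Del
SHMDDRTTCCDEQFNYHKTPDRMTAQWGFHFDRLSRRKIRDSKERPWGGDNVHWTYWGGT
MCVLYTPDVWQMKHDKWCHSDMGRRCHQIRIQSGYDSPCKNEKRSGKNEGTYQISGGLWI
QLGINFIMENWEIQACCMVMCTMGGDLANYPVSTYKKCYIGMTRLFLGNQQHYRITEALA
HGLTQTYPWRNNWIGSVRRIPHRWHWWCVYLLHRYQCYID
>Gypsy_Galadriel_RT|RT|Gypsy|Galadriel
SHMKDRTMCCDVVFSYHKTRDRKFRQFGFCFDRLSRRKTEASKERDEIGKNVFPTYWGGT
MWVYIIQDVTQMTDDKWMESDMGRPCDQIRRQSGYHSPCKNEKRSGKFVVTYQESGGLWC
QLGINPIMQNWHHQACKMVMCTVFGDLQWQPVSEKKFCYWKATRAFLMNCQFKRTTEAHA
NSSTQWYTVINHWRGWPRRICHFLHWWCVVLTHRYVRYRQ
>Gypsy_G-Rhodo_RT|RT|Gypsy|G-Rhodo
SHMDDRTMCCDSQFSYCKTRDRDTRPWGTCFLRLSRRKTEFSRERDALGDNTFFTPWGGE
MWVAIMQGVWQMKHDKWQRNTMGIPCHQIRMQSGYISPCKREKRSGKREGTYKFGDSLWI
PLGINFINENCGIQNCCMVMCTMEQDLANYPVSTKKFCYIGAAMAFLGNQQHLRSPYAYW
HNSTPHYPVINHMRGDESEIDHFQEWWYFVLWQDYKCYIQ
>Gypsy_Reina_RT|RT|Gypsy|Reina
SHMIVRTMCCDVQFSYHKTRLRMTRQWGWCFDRWSRRKTCADKERYWWGDNNFFTYWGGS
MWVQKTLEGWQRMHDKKKRSDMGNPCHQIEYQSGYISRCKGEKRSGNPEGAYHISQGLWI
QLGINQSMENHHTQNCCMVMCTTEGDLANYPVSTKKFEYTGATRIFLGNQQHYRFTEAYA
HGSTQVYPVITHWRGDERRGKSFLHDWYVGLYERYVCHRQ
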