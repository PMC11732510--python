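>g00000|p0000
HGGKMNYSPYFEPAAMLWPMLFAEQFIATEGVMTPRCMMVINCIHETIYNPPQEKFKCYFQHVQDTWWNDEWNEVPNIKFAVLMHSAIADYQKMEVGWYRSPFSRVVHLYRNGKRFEIEHWNHGYKYMMVRNKVKWCKMYGTQRPYHIFC
>g00000|p0001
FWTDPLNQHYLPPECKSTRDWTVMWAAAGFENANEQAHWMTQPENATYVCHHDPSHVSDSVENPPCQPTTHRVVEAQFNWIGLQDIDQTIIMFFHLCSNGCSDDDCWGHTPEKVIRCRSTQICMSEGMRVDESPRYWTSIPESSRKIKATMIMRITWI
>g00000|p0002
DSYDRTWDCYDENKSEWFSCLAHHRLCYVWFIFDAMDEVLEQGMGMPMISVEDDYWFYFMLWAHNCFLVSTSRTQRHESEWNHWEMCYNTGTRPYKKQTHQFNSCRAYLKRMRCNNWALPNCNFEVELSRNTLPTQPKNIR
>g00000|p0003
ILSMHTITSKRAIVNNQQNKEGGKYIKINWVIGVLQCVHLEKTTLSLIMFHRSCRTKCQFPIPGLMPFYGHGCKSREDHSLWQPSSHGKLDKPDDEGYAEELALEGSEPKKTEWVQAQPSFYV
>g00000|p0004
DHATWYPQQNYPHMARQKVSHCDEHKWGVQVKASFDSQFGWGRDTDMANTCGSPHPLVGSPRIRQIAYRFRGLVKGHCFGECLFRWGNMCDVLTCNVVAMISCGTLLYHAIECNYNPHNSNTNENLEPTDMRKGIM
>g00000|p0005
QNDTWDFETWAHELWCELMRKDIYSDTHSAVELQMEDGCFDLINGAHSGKSKVWHRGDKPWDRLDYQDWDCHWAWPCNLNRQYETKSVYGLWWIWKISLKIKDCSNQTFFGHSIHPEDQS
>g00000|p0006
GPAKNGHPNERCYFGFYGPYYAMPRHHAANCFHCAWKFRAFYVPCHAFADPDEWHHCSQMPDGNYTPMAVCDQTSLEAVYFVKHMAKERMVVHGWMCAYNCMMKYWDEKTPRNFTAQELYMCKQCGAMIMGQEWYLLVGTGRHPWCTMIIC
>g00000|p0007
GPCQYYVTEYFVVPMFMGDDTWDAGDENKKFQGILWFRHVIMVQCDYAHYAEFCLNHDTTNDMPKVIMDNSRGYRKKSEPRMVLLGWHQKWWAYPCLAMEIHPTWHNAIYDVQGSGVCDSKDMGMRVCNYLSCVNVSVCREGHNPWAEITMMSQGCLVNCKINNYHKPVRLTLYGDTGTPMCSCYVHDVL
>g00000|p0008
DLFKPWTELLYCMWIGNHWCFCRGWVWGAIYSCRWYRVTICRDIYNMWGYWIHDWEAVNQRACLCMRQPAFVDMCWEKMRWRHCRYASELMPYQIRLKILGFDKGTTHPWINKQYDYQSPVHRGMQFCSTQHQCQ
>g00000|p0009
NPKFRLRICMPWVCSGQIHLMQPQIQHPLNALFICQVIDPDVDILDHGRYISDNKGTRDGTYPVYRPFIPWHIAQKSFQQLEKRECLFTTWTPETRRQTGQMHHELIKVQQYFMCIYCSVMSKIMEHHYHF
>g00001|p0000
KWMYRDNEAWHEDQLARGSLMLQYSCLFDEFYRVQHIKGKSCGLQPRDEHGSYQAGTWNHIPVHEADVPYCISQCKPQLEYLRMCFCEFKHITADTMKGMFVTHAVGQVS
>g00001|p0001
VLTLGLHSTDEIHENNGYRQTFRRAESMPNPHRFVSMEFIHCKKGIHIPLESMLRSTTQREQGGDIAQRSDPTAEGLEMHQMQFRRRCWNGKMMFGISKALFAYGMICWWEKIEQSSQAFMRIKTAGGYFAKPETEREVFRTGCNLLSLLLLK
>g00001|p0002
EGGFSDFMHFIMQYVKLKFYCFQNGWKNCVDIVWWTFALCYAHFALCVQITSHTWPIWWHCVQFNHWHEAHYFLYAGTCWTDNNQHIFGEWVIQLGHYHNWGTDRTTYRYGMFCKRSAWFGTVRHLTITSLVIRPHMPMDYYAWMDTKRTMATQWGSVIKHAFHDSKNGISLNKNVGMQCYLFSTPWCMRWPPINNWT
>g00001|p0003
RWCSLSGLTAGLVGTFHNQVVGRPISVLWDESHNLDSRDGTWVMIKELFEICLQQYVPVKSGMYNMSHTAFEGWAGNRSIFVDCFLWRNMQPHCFSPSAWIWNMTPQEPICDLGSDAYHMFFKSATY
>g00001|p0004
NIFEHVASQACRQHVFKDPCESMQRPEQDGKDDQRIIFMNWAWYHRTQGPVDLATSARQDMQHMYPMCDVRTNNMRHLLQFACEVRRKDLVMPIEPLHGQHNGSILWRRHTIYVQTMRDYTDFNSDYHYSLICCPSWIWGWWEVRRTMMIVWESGE
>g00001|p0005
ENGFCHSALPAGWYVESLELWVICWYMFMQLIFGAGYARSKNFQRRLYVNQGWPVGYDMDESCIEVCHVQRYAQRRRCCSPGAMCRHTCLCSNFYQHVIWGYCRGKPAFDRFLHFWMQRTGCL
>g00001|p0006
EAWPKDSMEYYWTMHQEPCARHQSTPTQWVAGIGEVAESFGYSKDGYSCRIRGDAGVVQREIVYKSWYGQILLGASQTEFNWLFNYVVKGVSVIGFVWIVIKNFGGGMDSEKPDK
>g00001|p0007
NNVSDTMQELQSTFTNQVKWVTIMESVERQAWLGASHMEPITQRGCVWPWRPKILFKMAIGPTPQPGITWEAYVPTNWFKQFRGRTKYPSADRWPWCVVPKRFQQMGAETFC
>g00001|p0008
FMNVVYVLDYFPGTFKFVPPHEVSRYNEPGMLNWTKTVSNVLDGQIKKECAQHLWPTSYCIWLWECVKMWFYIFFMLVCAEPSLPPAFYHWLFAFHKKMLAGYARLRHIMWHCAVHDNTNEKGAYLDVYTGEMNVYWHNDMCDDHHRCDQQRRQNRCFREMGKTQKGTQKVQYQVNRTCLPCSRWILWKTKHG
>g00001|p0009
FKETYCCAWCQHEFQAVNFFQPHHLWMTPNLQLREHVITWNDSQGVLCCFPTCAPKKTWYSAENYCMIKGGFDNKRPYHVIQTIKPDMCFPYYGDMKISRNPNQWWYVDLSGPCFKCKFVHITNCFPEFPLGNPAGHVCHEQTCVQFWGSCLMVTMCKIYQKISCTQKRIDKCCKTFMYTWQNNPLIFCISNETAWQNKTAAMGKMAYQCRMQRYDYLFI
>g00002|p0000
ALDMCVEQQHFWAGHNIDNRRLHAMPKYFTRVWFWKQYNNCNFIIYPREHVDYKIMKLKRGEKCKLSDISHTTLSFYRPPFLRVRRPFYIIFNHDRQYDWSGLPHDTELKWNKYIRFSSTLFPWHAEWACCVIQRKRLMHANGGVIDPMCHPGYSMWAFWMENRPAAKACPKCVIVPPKQFGVFIRHIWFFVGHVHYTTFFSTFFFDKMPCEDGEWIDQYSPIKHTTLVQQGFFWTVT
>g00002|p0001
TKSEQAYVESTANKPVRFNNADIEFQYLPSQQAVEEMNSGWPTLCAPKKHELGVEYVISNLTTFWAALHKLLWWHGQEKRASRIFMGTNHTPDKLWHKYKTCIEVNFCKCLRHEIETCRHRSDSWNPHERTFDIPIYSWNSYA
>g00002|p0002
NESFRHQQWVKQECRWRMPRNIVIWSSTYYMIRYPAALSVIMMCAMMVEVGMRDWYYAPQVFDTGCCPMRTAWVWSIFWKLQQQPMSIGWTREAWWGPAIRITWDQIEHLVSACYNPITNNFSFDNTGHDPSDMMDMGEYCHPKAVFKWYWKRTEYDQFF
>g00002|p0003
DWDWEHFYCVHYSGMEKAQNGAWDHAIKMHFSGHLGRCHKGTIKLTFTWGESHFCPWVNKYQYQQRDGCWYPEDKIECPSCHHMPKVIHSTVEELYPPHYENQTTIGYNGDTTNIQYNSVSLE
>g00002|p0004
QTYEDPTCPGYICSHKDHDGNGQWNAYEHMPHKPLGKIGPMKRTPHWDTKITQYVDMSCMYFDGHGKTMNDCYHWHPQCCKDGEHLHHLQAYKWACCWKTQCIHLSCWLIQGRKLEFVNKSWEYAPGGLPKRYEFPKHMQWWTHVREYFQQWQYCAENKCFNKSLVSLIFGIIE
>g00002|p0005
LDVNCHGELEERKSRWVWYRLCFTYVHRGRGSYYDPFIMYDCMWAPANDQIQGCEGEEMKTLMRVNALAPCMDVCQRGNHGGAQCECTMLNTPMHMYNLVCCSWCAANDNQAVGNI
>g00002|p0006
HKAKGIEHQYEVPDAVFDQRVMHHFPWCIICNYGRWGWRPEGDVTCMFSNWRDINWIEGFEHFMVYENQEMFIHTFMNHWHHQLREDRIVFFVIDFSGNTPSYGVNFDHDSNAVNKDLWNLPNPEDATAGNLWFDELGLQH
>g00002|p0007
QAMWWNYFGKMTKAQFVFGDHPGANRDKCAIGVAPRKMFGCWADRLMGESDGSGYEMMMSAMSCMKKMPRVQYQGDCGDQQPILGWAHNEVLICGNGANHTQRVTHNGFFDFFQGAKFQFNELVHMKCATHQKTELMSAILNDMQRFKGIIWAWACFGVTWIAPVDTARLWVALFKCIK
>g00002|p0008
AWRNWCYRLSFCRVDFIPSCWSMMGFIREYFGDIIQVFTHKDVIRAQFLQEMTELEDLLPVRHLQTQMDVGKVFWFCMSKTITDGDRLQFRYCHVVVFNCKNGKICCSAYVYSADH
>g00002|p0009
ECWWSGVTHDDKTCKIVEQHPTTTGGDGDSAESSYIATGSAANQNMNDCHMFEKKGWWALFHACADPCVTGQYDNLHGCPEKWHHWNNFPIMICVQYHGDHHEGGVKTAEYCCMGEPPEMLTCFNATYHSFWFACLAYP
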