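>Sf6 synthetic TerL archetype (headful_pac)
PLIVTFATEHLQPQERDSALGNTANDFYCYPAHGVYLLLLVRGVGFQSGVNAARRQKVPTNQDLSNRSRA
PLRILSPHIIKRYYYYGYSIKIWRVASFANNAVEEQVGQPVTALLKTGWSGWAAPGPQIIAGNVPLYRPL
SLDEKSPVSSLACLPVVFGPPLLLSLSLEGIALNSEEPGWGNFVESARQLSTGQAFWVSGQSPNWVRSEA
NGGPDPLFRLEANTQPLKLHCSGQGTVALIEKGEFYYMGDVSWASAAVLKHEAQGEYPAVAGPAGTFVPY
LRLQNCAEATVSNNAVKIEKAQETTTNKSNYTQAYVRSGFHLITQYICVSNLGGVKLTESMLEQLFDKEW
LIVRKCLRNLVPNSGQYAVHTGENSLYAPKVMIFYTVYFESTQLEQVSQEATYAFPEDLFGGTVSDGWDM
KSPSGSDSQGVTPVTGEEST
>933W synthetic TerL archetype (headful_pac)
TIGPEFTKVLSSFEEKGSHITVQRSEVECQSPPHMNNDMKHPRALLNIPVDRIRKRMIIYIAAACQTPLS
LYLSPPTRLRTLITGQEKRAILESIYDGSASPPLPILSVSAIVARTNFLSTGYEGYSHLFGNSEPIANLL
GILGAITHEHEDYATTKKSAYRNTFWSGLYRVVVNQWFVPDADEKGVGPLAIVDMSRPGVEGANSQCKPG
EPVATHDLEDQTDRKLQRLRKNDTDKAATGTLVSIGLIQFRLYKGSGRYNVFTKPGTSAKLLVDTEVTAR
QRFDCQDLNGCPQGRHIWFTNRWITSKMRTKAKKVLVLDTASSIGAGLVSMGYQEPNYGAANSLPQIGAP
GAKQALNGGNTNPAAHGDRHKDRRNKEDRTIQLGESSSPYFQFKRALADQESLLAAGILLLGFQIHEKFD
LATHT
>T4 synthetic TerL archetype (headful_pac)
PIIWWVHKERGRPPIDRTTLSAEPIPRHVGRGWSQDRYCYTQPPDVHQAIGFSGWLLINAYDEGAKLGPE
ITAAVLAVLKFVHLGAGTLIDGEVVLDGRECHFKINKNRDNWIRVSCRQEPPDSVEPAWLYDYLDNYQDA
NAVIVSRINQPVRSRPDYQARVANEYLVYLDKCDCNLLGSKEFDLDIVREADWIVEFLPLQYVSAAEQEF
RDHRYDEIGVLTKNHIIGVMDDASALGIDCYLSYTISRHRGASFLLDVEYGAVPFINSKRDRGVSADVKT
KLDIFGRCFMLQQDVVGHMHLGESGMDGESCTEGSTTRVTKTLFSAEESFLVLVAVVCNSRPAIIGYTGQ
IWISISKLYADVALAGYTDTDVLGTKVFSLNQVAAEVSSLDIDPTSTQFEYATSPRFGQIFHYRLSIFAV
PPSIIDEKGNNVDPPTLPRVETLLEAFCPDKERGAQSDSNKLVPIPNIFHGAHAVLLFAAHYFFLHLKTA
DQPPIRYGSD
>P22 synthetic TerL archetype (headful_pac)
FPVVVLRAAWRQELVSRLKKGILLPGQTAKRIEVKAANTPYGRKINGVAIQLICSPCSNSMMQLIDYTAG
ITVVEFASVSLKALGPGLTQHIIVNTPDTPGDNCLTGAQLGATCIQGFGPAGVMISNTIIEQARIEEDES
SYQNVLVLPLIVEDDTARNLSEFFRYSYNRAKYVGDKSLFVPFANKKTQRLVERPQGHPPGDCEDTPAGL
RIRSGTPLFRANFKAELLLVSTPSFLLEPVNTKSNGKLPGIFREWDAAHYHAFYSSDGFGAHHEVEDIVF
NAGQIAGAGCKFYSLGLGRSSTGYANVTRGGISPALPDIVCKEFGAVVLDNNGGERAKMVTLKQGFGARN
PQSASVDHKKSLKTFNTCHLDLSPSNIIIILTIHSGRNDSLSINKEYLPLPTIIFGGKYNGLIYGVDVIE
KLVCTKRDEFPEPLVVECLGETVATAWDMMAVEEVWDRCK
>lambda synthetic TerL archetype (cos_5)
DNEPMILAALGDSGHIDQQLQSNLDDISRQDREFSELHLNKSEVHRLRQSSADTSNKSYYKRTKSLADTE
LDYVYAAVIAFGELFNAWETTGLRYVTKIKYLAETALSYVLPAGMELVTQAAAVLRGWDYNADQETVDQS
LKLAELGYHGARCKVSYKNTPSDYAKRMEFGARPLNEKTELLEQLNQDCACAALRSMYIKEVVLDLEEGK
NSEIAVSLGFLSVPVLSEPHQPVDVGVHAKPPASDPRVLQGNEKVRMLIATNNQMANGAFGEPQMTRAMQ
MARDNKFKSRGMFSNTEILLRTYGSRMLGNVVGADVALGLVHLRRSTDVKPNFFGNYGPYLEEIIFEERF
CVNPNDALSVEKAVLSPGADLKEWAGFLEEEIQPTFELGVAKQEHRKAKPEDAVLSDNYEDDGKG
>P2 synthetic TerL archetype (cos_5)
GGGSVLECTFRPKSFGAIPMHEEPTYNAGWIVIALWCREAKDRVSPFTTTHLWRFPVSYACTTLEVLLIV
FRRGALFGEVENIGITNPEVGEFSEWMTQQLDGGVLPPRCEFWRGPAREAASKHARNFKGMAGGLPKLDT
VIIIAYKIQNLFLKNTVVGTKQQVNVTELPQFEVSFIDVTVGKSPLVGYPVAFMVVELGGEAGGDYSLSN
HIVGVAGGPFVEFKPELKQIVAGVIIPLLIYCYDEAGGHLGIQGAEFQHWERLTCAGPEREIEVSLKGPE
RNNFNMVRQQNSAGRGKFRRVLLGCREALMDDSCALTTNFPELPKQGQGLNTMNNIDMLSRSIVRTDFGG
VYSDGKFSARGHVGEDCDPPNCTFANPVQSITMALFFMDATNMDKWRKIGKIALRTVQLHLVPWLLPGLE
YHLNAYNEDS
>HK97 synthetic TerL archetype (cos_3)
VRDAKAPDEPLQQGDEIAFSHTRKIDCPKKINHGLKLKDDKPGLDILIGHPGALDADNMLDLFLPPTIWA
VCSVPINMLPEVQNSPRSETAGGELELLGGLEPKDTCKGASFRRALSHAMDKPIENLLCGLFCGDHIYFY
KSPAMDKHAQLQELHGGMAKELKIKKLVADSTAYIRGLGVYVLVDDCRVITLKVAPRQTEPLASAKRLRR
YRCAEMQKLDEGAILACMDKLMLVFKNGAITNLANKNPRERSGAYTLDFSETSGESIKYPYLAQTVTVVG
EPFATCQDYCGARQGDAQRVVEPAVSHQKSDTLGGKFHGLPRARRAPKPEESILTTENAKTLTGTATGWS
SGDLLLLNFPTVQDVGQGERDEDEVKSGSYSCIDLGVDQQRKHGKQPFAVVIPKIGCGDGERMHKGVSAG
>T7 synthetic TerL archetype (dtr)
DHQLHPTPQRQIKRIKVEAKFGEHANRARQMQWDGFLEGGHVVFRLTNKTLVLIGQPAELISRGEVEFPD
QKNLFFLSLFLYAWAQLLLFYVSGEVFYSIELVSVTPPSGEGINFGYTVGRKTMYIKAGSCRLYQTHLKI
CCYEIRGISLEPNLRIEELMHGVDLLGSYSLYDHHECRVNKLYPNFADIKKGRLESVDQNEVRNILHFLG
EDILPWLDIRLVADCLQVPRLHIDERSWRGDHTSCNRAKFSPLSLSEQAPTELEGVAGYANSVQSLGPFT
IMRPNFASEFKNWPDEDAMTQSLMASNKFCVLYFVGAESGSRVRARLMWYDKVTLNPESLVYTCEANHRH
GKRMYWGPGSADPPPLGDGSVLLFKIMTFVGGQIYGINSKLSEDRVRLFCSESFIIGATDVFLAGGFYHF
NVQQSLVSSCHDFTACNDSRFELLIINPEQISRPDTPVDNAQCLPANITE
>N4 synthetic TerL archetype (dtr)
LVGVITSPAAICEKYVGENGAKRAAFVLGRKANPSADTSKISRDFQLEHDAYLRRCLNDECEQQRIKGAG
NQGLLVEERVIHTAFGTSVNADRDLTPNFRQGLVSDSSLLIIPALVYCMCVNENIIPIVKVMPNANEQVA
ILVSIDELFEGEFNIDIRMWLAGHSMAQLRYGSYLDGGGPLTEFVGYHVAYKFSWLKPPLEGALLFAIAT
HLITFNTNSSRNSADMPSRLVRNSIMKASNRNDNSVDNSSSLLFGYDQHDAGKSLPLYLRPVMFALVIIR
CRMLYHPNKLSLYEPKTGSDVCHKSIDHSAADCDISNPMDVGTEPVTQTGEMLRFSIRFRVQAFRGQYVA
SEGTWQVSQIAKLEKDDRVDINDKARLRASEDMSFVNESNLHIEYFMSMKGKSIKFAFALPDLSDKSRVM
RPRFIGQNTLAEKFWRGAFQQAEWP
>Mu synthetic TerL archetype (mu_like)
DKEIVVVIVARDSSTTMHGVTANFINVISKHVSSVYANVLKNAGKHAHWARSKLDVRVSNPNGTVDKLGQ
KVEYQNRTEASLLAESTGEKVYGGGDIALAIQFANFTFVKTAVRPRFIDRFPDAKLVIEFNVDYNDQEPL
AEDTEEPFFNESGEDVLSFFEQELFAGPGEHVDTKNKTGSGFPSNQSTGKNSVLQLYADLQVGEAFDMFE
VLIEKTRLQHVFKEQVEWTGLTSCGALQIGVMNAEYPKRREETGSVRNCIPMSANAVGKLRQDRPQKASS
VPGTGYSCITRLAAVGKLRYTKCINRVILTKIPWLCGGEYQVKQGTELLLGTTGIYGELLLKGMTAFGIR
GSANSTVCGISGFKPQLGPVGRTEEPAQLIYSGPLNMSATKTECSAYFHEGNTNRLAGDTAKAAALFADA
GLLLTLELNRTDGISLEVTRENLRPARIKNGTPVD
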