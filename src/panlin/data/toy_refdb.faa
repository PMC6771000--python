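>catA route=catechol_1_2_dioxygenation
SQKKVCQFCMYRSRSMDTLMIEWSPKTMKLFCNVCVTGPESRICYKVQSSEILLAMERQWRIYKHWICLS
ELDQLHFNQWKETPRCHSTKTTIVGFQPDTETASSSQLRGSNLMNADFDKQQLVNCSNPNNCNSHPAHKY
FGKYVAFTCVGWGKQDNMSYQKKKTHEHADCSRQLREWMWELQLKEIFHQPP
>catB route=catechol_1_2_dioxygenation
YCHDHYIWLQLGSYGSGRSKRGCCKWDLRFRHTNMELVASLRQKHPDNCPPCSKSAELEHQDQDENSEGW
YNKHPNGAEYKLLSCCGLQLKWENMLTGYHMMTKGAITAVMDHNHDQQDGFQRRWSHDPWYFFADNMIHT
LTYHFYPGPMWGYWEEMAGKYYEVCRTVFVDMLHASHQKIVCRRIGAWWFADCTVEREINRVAEGHYSHY
LMKDWAEFGDAQYDGMWQSN
>catC route=catechol_1_2_dioxygenation
EVTARCRTDKDNWCIYHDLMQHYMGYWLANNDPTDRDRKAYENEWRTKLPSTAQDGTGSLFHMSPWVSPG
KDIWKDQYVGLMFGFYRTTYDVCLNIDETHHWDWWNEEGNELDMARCEETCKNMQTITHYMRVSVMALEV
FFFPNWKGAAIWMVDCTDCKWQCTTTWFYHTNSPPPSRDTMHMYVTLSIQPFGCDKLEKPFHIMIRHKIE
QFGSWQWVLSHLMYTLQFTNMSPCGERA
>catD route=catechol_1_2_dioxygenation
NQMVWDYPPCPRNCMWRDYYETKNKSYSWWCGRNCCMPEEDNANLLQMRSWSMLFNDWTDSDRCLQRKWS
FQRHRVTSPGSIMHHEYDCWNKRIDRENWWISPLDIQYARTYKDGVVPDDLNAQMACLRTKGYLHKAHMW
RSMDIYAVQGSTADQYAQDQPCQVVAFFLDVSTEAWGQWAAAECTPYTYFGTFCQTYWDSTQTTKALF
>xylE route=catechol_2_3_dioxygenation
DQMMRMPCVKETRCEAGCRMYRPMCCPAAFVLRKEICSEIYNLMSGPVNKDFWMHKNMQGPKWEDLMQKW
LDDYDWGCHPKSPKPYKEKTFWNPHWAGKLLDFCNINNRMPNQPHFSHMEKMPMIYMTRNVDWVMRMGSF
HMTILADCCVTTCCGNHLERHCRWAKTRVKIREFPQDMIMYCYKSKHSQDRSIWP
>xylF route=catechol_2_3_dioxygenation
AQFSMLEREKTWYYNFTTYQDMKTIHCTSAKLLWEHEFWWAPFEGELYNRLACGFTTVPNPKQSSPCRIR
MVHWTHLMSQVIMKWHNDVIHNLTMMDAIYWPPIEAHHEGAPWQKKHDNNAKGERMPRYTPVLYSQWMRG
YPSLVCDMRTKPNYQKYDYEGTRYRPHADGAMSYLVYVLHYFKCSPCFNMTGWKTFACIYAIDWQSRQSA
VRRITIAWFDPFVKAY
>xylG route=catechol_2_3_dioxygenation
GQMASKQVPQGFKVMHSVWGRNKIDGMVVEQCQHKRKTMYPGSKMDDNEYVRRNCILWFLHDDICCIFNA
HLYPVHKKVYYSMMYGHVIFNHVWHMYRFNPQAGVFGHEEHVAGCNGSNSPKVLWYNQGTQWGSLEENHD
KQHYSMWKDAWYRDGACFNCYLGMSHACVDPISCVQKFYHLIFKEAGDKVEADMGLAHKKNSLTMGFHNF
WLVQHFRHFWLALLVREEPAHDAWCAWETAEDRPLFCNFNQT
>nahE route=naphthalene_salicylate
AGVMPLEVSYVGGFWNLYPWYCIRTDHMSDPGFMKPHTCVARHIAREQRTRHRTHDVDNFDSDQQCESMD
YGAWANYNNIDNVCVKMEPEGRCKNDGHQYTEACNEFTVTGPPENMISQMRSNGSRYDKWMWAASIMKKW
CSVQIEQLDIYGEQEWVYWFFHLVRPVPIKMCRQRMSWNKDSWQVVSMCAFKRLAFYYITRWVPIPHHPN
NIKAPNWMLCEHIIISDHEHQAHAYRFECLSNVHGLFYE
>nahF route=naphthalene_salicylate
MCLLGDAALCYFQQLVDFGDGHSHVSWDYPYIYNCKDWHFNKCTTRPKMMECGLEDVINMRRGTITKDSA
SAFPWKDFVRDIGETPEQKCKEFVRDVNVRHMMRFHFGEAWCVASHMGLLMIMTKIDIDEYCLTYDEINY
FEGVAIDEWAHWPCLYKMMQETYDTTRILTETWQHNCWHCSQPCSPSTFFWMKGPSANYGGVCILSDKES
PLIEWPHKRRLHQQNCLPYMHNECQYTNAYKGVRRGY
>bphC route=biphenyl_benzoate
MSQEHIWRIRRIKVNDRNMRWHKEPKHQKLKGDTCHQDQRQHAVHTEESWVSFWQEDVGSDGGGQWWRFY
MMRSYNPRGHPCHRYMIKQMAMKRVYPIKEWTVHHVMRLKPTHTFKWYWHTWYARYSFSDLPLQFPPPGH
GLNIKGFQTGVNEIAAHLSDTFDQSPDDILYGEWEAKKPVWGYPCWDNSFGLVFQLDRTNEEKMNFMGQS
QAYAYAMDCQRDYHHGLEKFCIQSIHSQTWTWK
>bphD route=biphenyl_benzoate
HFRRTELFVGDNVWCHEHMGCMCFACKVSCAHQRTHEADCVGTNMLTACKIMRNGHSFMMSRLHIKFPFP
SYDSCHEEEATCIQYVDYQEKWIEVYYYVLEPFLQWGGRANRNITIRLAMAWPILPGGKGSDTHNEISGD
MEHLNPQTCIAAFNVSPSETVCLTLTWLCHFLNLEHQAFVCKFDKMECDQVEHHIFCMIHGWPKFTVAWQ
CSDCDLPKDEVYSDTQMDYKAFKCH
>benA route=biphenyl_benzoate
WCNWTWETYHLMLGYYITISNLDQHFEYDSVANNIQKKKTPIWTWRISHGLYNILGQINIHYHCIMCHEM
RYIVFSNSSMGMTYWENDQYCQWTIDWWNYAPAWQWNCAHREVFLFLLANSWHVVYIVNCGQEKSDLFMF
YCYSVVEWNYVNIDDITMLFNPYRPWKWIDKDDVSFTCGRHRVCAWMMLKQNEPQDISPDANLYMWFKDN
ELHECMWEKFTKYFCNQYVVPIKDKIAFMIYLYQA
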