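>Ale_GAG|GAG|Copia|Ale
HGWQTTEAYSGYRGYGMHQPYWFTQQTCDHIRCQCEQFARIVTTVVCSAPYNYTHTPFDT
AGHARMGPYNPDSGSSKNEFYQIDFTAADVKYCMDEDNLRPVYYYKYKTKGTMQTEGINY
>Ale_PR|PR|Copia|Ale
FSQVHSKKKHLILFMAPMLGRLRKCHWHSFTIKRDKMLPWAYCEQQTWYTADNDFHHHQM
FNWKVTFYVQHNWTFAMPHPKAIGCYRDQWAICNAVYPMC
>Ale_INT|INT|Copia|Ale
LPRVIAYLMKGYPLVMHHYVQHSWQCQFLATIWCFAIKHVWCGAPTLTHWTQTVYCRQMH
MHWVLFELWQPLVDNTPKPVDQEIDQPKKLPVKCWPKSEDWVFTWIKNLESDVHFSALGA
TCDGPGIHMGVMIERMYTMTWPNNFAMNFS
>Ale_RT|RT|Copia|Ale
WPRIEGQQHAEHFMWTQMAHCLYVWRDNAMLDKQPYTGYNFSRAQAHYGKCKIINFAENE
CVSWPMKVEDGASVPSHPWACLSFMVRNLQMNWQAFRGWIVWICLPVSEKIHLSINHYAD
WGGGLFQPNSIAVRIKYQWNQRAVMASLCCMDFFSCECPDLQLYTWYWLMCMSYPKFSTA
>Ale_RH|RH|Copia|Ale
VAVCIPVIPRVFEDQQIHNWYVRINVEFKFIWDKIPDAYGDPRTAEKCFDIWQVANFNMD
AMDHHTQKFTCYHWCQKAMNNPYEQCHQKGTYIRYVPFGSKEANWKYFMW
>Angela_GAG|GAG|Copia|Angela
VLSEDRQGQLLCWRKNMQIIWKLMISRPCWRHKNQCPIEPQPVAYRLCHWPSQSLDSGAY
DWQCDMMVAKHGYQNEPVDGVLHKFHKRCEGDIYLKSNDRKHNVQTIQNIEHSCDHYAGK
>Angela_PR|PR|Copia|Angela
TYMHFRETDMMCRHWDCEMNSPWEPHYTALIDQSSKQSGGYECMRCLAITEINYENMHNR
TRMMYKALQTCWVYVQCVEKQLETGSQMINDFEMTNEQMN
>Angela_INT|INT|Copia|Angela
CMSMCDIARQGVTCKFVEMQATEEFGRPGYPHWETALRRGMDCSMETTNCMFPRNWAFPQ
CTGAEPHPYPMVFPAWMTWRSDAHPDAHHEPRFIKILANTHEQRHARGCTWSTGGAMYIP
CMYWGIKSVDYQEHSGFMVFWGAVRKPSFM
>Angela_RT|RT|Copia|Angela
RMKECHAHSWRQGVICWWANHVWGGMRLSGDGACWKACFMTGGVSRMSLQKENYMPHILQ
FIWKGFHMAFCFVKLFCQDRTLEFGFEPFTRDITIIDFKWAADGCLKPEIKQADNICGCT
YYHISHPQYYPSYAAWWEEMHIIECGLAHHGHAQHQNYQANNFYTNIFSIKHSNESPKQP
>Angela_RH|RH|Copia|Angela
DECKFVYDHWMEIKGTSFFTHYTVYCIIVVTLELNVCWECIKVNGLMLEWVVQVPKRINV
FAWWCYSEPIRMYKETIDPYQMPDSFCLELEALLIISCIMLGDCMHIYVV
>Tekay_GAG|GAG|Gypsy|Tekay
YTTNDHLCFWKAGAITGPVFITVKFCLFYEVANMLGNMEDNGRPIMIKMIGNCDEPGKNV
AANGTFRQDFIRNYDQHMWMDGTVCPEWWIYPRPCQDKDPCFMFFLKFCPVKKVSYQRAF
>Tekay_PR|PR|Gypsy|Tekay
LNWFFVAIQLPCSMYSTYCHYVPVPLKNKRNKLPDCVDHIAMNNMHHIMWEGSYKIRGLY
FSKYIKKGSWYHNQMEMCKGNDPKTKQMVMHATIIEQNVW
>Tekay_INT|INT|Gypsy|Tekay
MQMDMSNIPWHLGKMVPVQPERMVIQDFHWTIIVCAPIESEHTQGCMSGPYHASRRVSVY
WTQIEDRNVKCEDYAAQYTRRFAECNICTRSKWTTIKEARNTAQLLLQDVNFELTYRTQV
AQHVTHPELWPYQCDVAFWRTCYWNWKHFE
>Tekay_RT|RT|Gypsy|Tekay
TDKDCMHHVCRGFHPAEAMYAIEDCQQCIQDWRLWAITHFVGFVESKYQMGALTEYRKWC
DCWFLEPCWGDWWDIYGQWGIKPPWIDLFSVRCFQDVCSFVNATDWQFAGPGTMFANLQS
ELCWPMRLYHGNDIFVVPIDNCFRVIARMSMALVWWREAIYDDVEQAIDHVHCWDNTWLE
>Tekay_RH|RH|Gypsy|Tekay
YMIWVHIHFMMYVNMNEKGNPSQTQEVFSPKPVKFKNCRPEVFPVITKWMFQDDIGHKER
DFFLRMSNDKDQVPHSPLVFREFPYWQMFGCFMRCRQVYINYLIDLDFCS
>CRM_GAG|GAG|Gypsy|CRM
REVIPQDPTFKVVPGATQCAIFERAFVVLSLDMIDDDWREIFYILPQGHHMLLGWVMMAR
VHGANWEFHEPCTPSMKTMLHMHQLYMRSTNFHSFWGLWCVIHNDKYTAFCAAEYKWARL
>CRM_PR|PR|Gypsy|CRM
WPPLVMAQSRVWEHKSFGGITAWWTISFITWFPDFSFGGLFASMGALNRHWYLHKHTYPE
CLRVMNGVAPFASHLTPRHNWVYCEKFATCSTEGRCSAPT
>CRM_INT|INT|Gypsy|CRM
YQSLRYFHRSTFNFAIPADRGQKFKEELFICEPSLNKYPSGMTMQKRFIHCIPAHIQNYN
PIAIATNEISCIQQRWQWVNRWTNRGFPVKPFCRVHTCRQRKHLSSQGYVRCKHWWYAPG
FSFPGASCFWDSHYRQAHCRDRQCWAPNEI
>CRM_RT|RT|Gypsy|CRM
TEAKRPTEMVACWWNCQPVPKAPILRTYNFHTWDMAIMFSFTIGEAWQPVEIQQYLCAPF
MVFHPPYKNDCKYFYAAYWETPIEERWHWITGGVYRCIPPATLWPIHWLHMCLYNRCEMQ
TDRWFKYSLHENIIMFCVIPSFYDGAGPNMILWTDQMYAMHAYRLFGVCSVIYVTYMHEW
>CRM_RH|RH|Gypsy|CRM
GPSGPCPQDRSISMIMPLAMQPNMQQTRKGHFPKNLWHPADARKAMLTFEGDCATSFAPI
QLVYDKPIYCGFYTIRLDCRQMNTHSPCQMILALLYKKDAQFEPEWCRPL
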