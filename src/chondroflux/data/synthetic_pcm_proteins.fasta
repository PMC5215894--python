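>collagen2_synthetic synthetic composition-based stand-in, 400 aa
KSASNGPGLAPQLGPGPQPAAEEQGAGGPPPGGGGAKEGATQKAKGGGPPGAPDGPGEPV
GSPAASPVPGPGIGPGAGGGNGGGALTNGRQAGPPGPNEEGGDVGGAPPGPAEEGAPGGG
RDSPAGGPAPQPLSPPRGRNPPDAGPGGAPAGPPGPPGPPNGLPQSKPPAGEGSPAEGGP
SGEAGRKRGGGKPGVATGGGAGAPPPLGGLPAPGRPDGPKKAGPGAPGGLSQGPVRESKG
VGGPPGEPGGAAKPGTPPGAGPPGPPGGPKGPAGSPGGAAGGAGGGGQDGQGANGDPDGQ
SGGGGQGPGQNNPARDPGGASPRNGEGQGPQGLQGKVGGRPGGAPGAGRVPPRAGQPGLP
GAGNAPGTGQAAPQRPAPAKPGPAGRPRGSGKATNGSKEA
>collagen6_synthetic synthetic composition-based stand-in, 400 aa
PGKGPEGVPGNKTRQGNADKRGPGDAQSRGGEAPPGQGPGPDEKGGTVGPLGQGVSSSPV
GAIGRGAPPGAVLLGLGLTPSEGTQPRLGLGGTAIGREAALEATKENSPGSDSLGQVPGE
IGGPEGTKEDLRKSGGPPGGPITAGGADEPPDPDGSNAGVDKDGPISAGDSPAGGRDGAL
AEKELGTREAVPVSPGLISLVGNGVSRTQQGAGILGVKQVPGLLGVVGGSEGAGDAEPVR
TGADDPDGGVPAPPDLDNGGRRAEGQGPGVGRDGQGGEPTAGAPDNTTPPVEPAGETGGT
RKNIGVAPKIRGGEPGGPLGERKLGKGPADAGAGLPGEGVQVELPRGDNRGGGGPKGPDG
VIAPGPVGPEARGSESGGTQGGQRKAKPALAGPPGPDGPA
>aggrecan_synthetic synthetic composition-based stand-in, 400 aa
GLVGRDTPGTVGWTSQTPQDPKGLVGISLEREVGYDFVPSPPLQLEEPGPTEGVLGQAPD
IDAETGAAPEIEAQPSGGPGTYVTSELSLVQSTSRATVEDIREWGLGKKESELPVSPRPL
SAELDQWLTETPVEEGLEGVSPSRTSTGSPLRSSLESRVLGSEKPLTGTQLTTTRLFQSV
RVFAGGLGTDSPSSPTLGLTGTGTSRSTPFEDRGFTPTSSGSELASPPRERIGGTPDSGE
TSKKEAPGDPEGTIDRPLLPRTGQEPPTAKEDRPSPTETTGSLDKVLLGVEEPWVESTSP
EVGGPPKTRGEVPKEQLFKSGDGVDASPATETTAVLVLQDATTPLEVARVKSQGLAKSPG
SEKSYTLPTTDGEGSKSASGELAVESTELRQGAKATLGDV
>albumin_synthetic synthetic composition-based stand-in, 400 aa
VKDEDAKAVNECKYEREYKKTSPQKVDTEHENVHQEFELKNAVLFYANKYLSDHEVEKKT
QVGHEVKLKLVFNDGLYFASELAACKCVEEDAKLEPSLFEIEPFDVIHEALEENDAAQCT
NKQSCGEDSVALGCYLQRLDPAGILTAPETFEVQKQRADNNEGRFDRASIVFCKHTYKRL
ASVLPVRDLDERPKQLVSVAAKCESEHEQAKNANCPCYGHFSFVVEDNAKKLPDTNFPEC
KKLEALTEKKNKDECNKPANAQEEKDNFLDFEKKEREAFCKNFPSVDFTNLKRDNVVSSS
KENYNCLVTCESEATKKVSKFLCTALRPRLFTLKKSADPYPPFLLILPQNEDTGELSPLS
DVETCDGEELSPASKRDRAEEFKPEVPLRNCLAYAHPVSR
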