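##maf version=1 scoring=synthetic
a
s g000.chr1 407892 18 - 1000000 CTAGAAAGT--T-C-AAGTTAT
q g000.chr1 789867F97--9-F-9402F97
s g001.chr1 24500 21 + 1000000 TTAGAAGGGCCTATCGGG-CGA
s g002.chr1 464308 21 - 1000000 GACTGAATGT-GTGTTGCTTCT
s g003.chr1 167368 21 + 1000000 -TTTATTGGAACCCCTTACATC
q g003.chr1 -5789F99996978925F0877
s g004.chr1 901194 19 + 1000000 TA-TAGA-AC-GGTGTGGCTAT

a
s g000.chr2 891285 44 + 1000000 GNCTT-NATTTAAGTCGCATC-GGTACA-ACCCA-TNCNATACCCTCA
s g001.chr2 61159 41 - 1000000 GATCTTTT--GCGA-AG-TCG-CCCGATGGGGAATGTA-CGT-CCGTC
q g001.chr2 896968F7--7974-99-479-8F0684777FF2F99F-F76-808FF
s g002.chr2 912450 38 + 1000000 AAATTCACTGTCT-TCA--T-GAGGAC-G--GA-TGGGTA-GCGGT-G
q g002.chr2 978979969FF8F-19F--5-749F98-9--65-5F858F-F7667-9
s g003.chr2 743934 43 - 1000000 TGAAGTCA-AG-AGGTCTTAGAACGTAAACAG-CCCG-GCGG-GGTCC
q g003.chr2 9967F939-68-11F1F99F6969667F083F-FF82-7F55-4F372
s g004.chr2 883661 45 + 1000000 AGCAT-TCNAATAGNGGTA-GACAAAGCAA-CGGGCCTGTTTTGTCGC

a
s g000.chr3 668260 25 - 1000000 TGATCG-GTCCGTAG--ATTGA-TNGATA
s g001.chr3 153588 24 + 1000000 CTGCTGGG-G-TN-GAGCACCG-TAA-CA
s g002.chr3 214367 26 + 1000000 TACCATAAGCCCTC-CCA-CAGCGGCGT-
q g002.chr3 5846F1FFF99695-59F-39F26589F-
s g003.chr3 544648 25 + 1000000 CNACATN--TTAGCACG-TAAG-TTGAAC
s g004.chr3 941963 24 - 1000000 -C-G-CTTGTTATTCT-CGACCACC-CCG

a
s g000.chr1 473516 53 + 1000000 CCCGGATACGTGCAT-CT-CGATTGCA-TTCACACTNTAAT-CATAGCGACGTGGG--G
s g001.chr1 838384 50 + 1000000 TTG-GCGGAAATGA-AATCT--GTTCGA-CG-TA-T-TTGGGGTCCACAGT-CCGNGTT
q g001.chr1 39F-5889815286-79998--974587-F6-8F-8-7F845989587298-F097F68
s g002.chr1 161786 55 - 1000000 ATGACGCGAGATCCCGCCGTCTGCC-TACTGCTTGGGAAGC-GGG-TTGN-TAAAAGCA
s g003.chr1 271699 50 + 1000000 T-TATGAT-AGNATGGATCAATGGGGGTTTG-GCCN--A-T-GAG--CGCTAGGGGCAT
s g004.chr1 28219 46 + 1000000 -T-CGTCAT---CNTTTCAGCGC-CGTCCACC-A-CTC-C-TTC-GGCNC-TCC-CAAC

a score=63.8
s g000.chr2 418197 48 + 1000000 GCT-GCTGG-CGATTGCCCTACTNAGCTTACTTTGGCAAATTGACCGTAG
q g000.chr2 787-77F99-85F9F2596789779969878185125F7F9890F67587
s g001.chr2 707452 42 + 1000000 T-TGGTC-ATA-A--GATGAGTGTTTTGGACTTC-CGCTCTGGGAT-A-G
s g002.chr2 303946 45 - 1000000 C-CGNC-GATACAGTTAAA-TACTAGCACCGGA-TGNATGCT-AGGTGCT
s g003.chr2 585461 45 + 1000000 AAACT-TC-AA-TGGCACTGTTAGGGGT-TG-CGGGCGGTCCTGATTTCC
s g004.chr2 885426 45 - 1000000 -AGGCCGGCTACCCCAC-T-GT-GATCGGCTTTCTAAACACCTT-TACAC

a
s g000.chr3 627987 31 - 1000000 AC--AGCA-NTCCTATTTATGT-GCNTAGAC-CGNT
s g001.chr3 895310 33 + 1000000 AATTC-ATTATTNTGGCTTG-GGAGAGAGCA-GCAG
q g001.chr3 7F288-109987270589F9-668F982750-3F55
s g002.chr3 252308 26 - 1000000 TNA--NCTG-T-A-CTGCT-T-TTTGACGG-GT--C
s g003.chr3 386207 31 + 1000000 GGTT-N--AT-TGGGG-CGCGTAGTGGAACGCTAGA
s g004.chr3 72278 31 - 1000000 GCTTCCGAA-CCT--TACATTCAATAAGATG-CG-C
q g004.chr3 296F80979-976--588673F935826907-76-6

a score=-20.2
s g000.chr1 780727 33 - 1000000 AGCA--G-TGGTGGATAGTCGAAGAAAATCC-CGAGA
q g000.chr1 9699--F-798F58F9F89868989791909-F7998
s g001.chr1 433675 32 + 1000000 NAATGAAGCGGA-GTCACAAGCTCGG-G--AAGCGG-
s g002.chr1 494972 33 + 1000000 TCGGTCAGT-TCAGCGCGTGTNCCTAC--ATG-GCCA
q g002.chr1 2F959F4F7-97694638738096732--99F-9989
s g003.chr1 187851 35 + 1000000 AGTTCTGAAC-TGCCGTACGCCAGTCGGTG-AACCCC
q g003.chr1 7726F8F359-FF17999669998469996-85F88F
s g004.chr1 172722 29 - 1000000 ATN--A---G-GTATGTAAGT-TGGGGACT-ATTCCA
q g004.chr1 F88--4---5-9F5F87F58F-F79705F1-9F775F

a score=143.2
s g000.chr2 348797 20 - 1000000 TANGTGACCAAGGGATC-ATA
q g000.chr2 2FF7886795F885F6F-848
s g001.chr2 114119 18 + 1000000 -GAAAA-CAGGT-TTGTGAAT
s g002.chr2 143318 18 + 1000000 -G-AGAGTTTNGTGAC-ACTA
s g003.chr2 353339 17 - 1000000 ACAAN-CCAGG-A-CA-CATC
s g004.chr2 771124 21 + 1000000 ACTCAGTTGCCTNGCGGAAAC

a score=70.0
s g000.chr3 986796 47 + 1000000 AGTACG--GAA-AA-CGGAGGGTTACTAGT-TAGCCGTGT-TCCNCGGGTAGT
s g001.chr3 381471 46 + 1000000 CC-ATGGC--CC--ACANGATGCTT-CTCGGCTCGTGAGCTAGTAAACTTGC-
s g002.chr3 989012 46 + 1000000 CTACGCTCAA-CTCCCG-T-TACCGA-T-GGGTGAGA-TG-GGTACGTGTCTC
s g003.chr3 962293 47 + 1000000 G-A-ATAAAC-CCCNC-CACATTACATGNC-ATNAAAAGGCTGTCG-CAGGTT
q g003.chr3 2-8-8FFF78-577F7-841F74658F76F-19699798995F88F-79511F
s g004.chr3 730970 41 + 1000000 T-G-C-TCTCACAATAA--C-TGC-ANCA-AGC-GCTTC--TAGCTCGTA-TA
q g004.chr3 4-8-7-48776888899--8-667-9759-805-988FF--769980779-75

a score=-48.0
s g000.chr1 467472 48 + 1000000 AAGAAGA-AGA-ATATTACGGCTAACGACAAGAAG-ACCA-TGCCGCTACTT
s g001.chr1 392202 48 - 1000000 -CNGTTCA-ATNAAACACGTGGCCTTGTAGTTGAACCC-C-ATTCAACGGCG
q g001.chr1 -957890F-82994868F89966F645687599679FF-9-96F5887054F
s g002.chr1 486217 49 + 1000000 CATTAGCGATTATATTAC-AAA-TTGTGAAGTAAATCCTCTTC-TGAGGTTA
s g003.chr1 316378 45 - 1000000 AAAGCCTAGAA--NGCG-GGCTATTA--CTTNT-ACAGCTAACACTAGCGG-
s g004.chr1 680228 41 + 1000000 GCCCAGANGGANGGCCGCCA--C-ATGTCG-A-T-AGCNT-GATT-C--GA-

a score=-40.7
s g000.chr2 119119 49 + 1000000 GTTN-TCAT-T-CCCAGGG-GCTGG-AGGAACCAATTC-CGGCGGT-GG-CGTAAGG
s g001.chr2 624756 45 + 1000000 -CTACA-CCGTGCC-T-T-ACTAGATG-TTGACCAT-NA---GAGC-T-CTCAAGCT
s g002.chr2 165442 51 - 1000000 TGCAATAGTGA-CAGCTGATCAA-GCNCTATACACGGAC-GATTTA--GAAGGTC-T
q g002.chr2 881F9999985-819846F9994-05871998F879778-397658--7879969-4
s g003.chr2 632533 47 + 1000000 GACCGGG-TCTGCCA-GGA--CAATG-AA-T-GTGNT-CTCT-TAGGGCANG-ATAT
s g004.chr2 138513 48 + 1000000 ATCGT-ATTTGGTAA-A-CGT--GGT-ACGTAACAGG-NTGAC-GGCTTAT-AGTGT

a score=10.2
s g000.chr3 302388 28 - 1000000 CAACCCA-CCTNAC-TCGCGAAATAAAGTT
s g001.chr3 744062 29 + 1000000 GGACCGANGATCTCTGCAG-CGNATATTCT
q g001.chr3 3856975188995FFF989-5657969787
s g002.chr3 296144 28 + 1000000 GGAG-TCCGAGCGNAGAGTTAGTAGGTTG-
q g002.chr3 7979-7983169F6650538689FF92F9-
s g003.chr3 19342 29 + 1000000 AC-TCAAGCACCTCTAGTGGTCGAATACTC
q g003.chr3 77-897F78F7F68958F3774F3776588
s g004.chr3 229365 25 + 1000000 TAGCGNTC--TTATAGCNTAACTTCT---G

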