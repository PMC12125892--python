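##maf version=1 scoring=synthetic
a score=-1.9
s g000.chr1 244682 32 + 1000000 SIT-STMKH-REHEVVT-WIFC-QWSFSQSARSIDC
s g001.chr1 40214 31 + 1000000 WSEVH-F-HGLPQDHSTKVDFCYCWFM-P-RA-PDP
s g002.chr1 25593 33 + 1000000 KGD-TSMSPHYMHHGKLEKLTEVPVALW--KNFLKM

a score=51.9
s g000.chr2 714556 46 + 1000000 W-YD-KHWWGKVNSSQGLMSA-YDQIEWSAASDV-FGVETKMJSCQPEHI
s g001.chr2 489636 44 - 1000000 AFKTDTPAHEWTFFD-KTAPCL-LQDMAN-AMCPVACPD--TITTWYE-M
s g002.chr2 502117 44 + 1000000 FYQPV-WHFFHAYSE-A-SLADESREE-VIQCGTGMQ-EWCHNCCC-LGD

a score=85.5
s g000.chr3 314831 51 - 1000000 ERMYTVQFKWA-IWSF-RMYRJWSLID-HTIRDYEPMAS-LTMACSLLIEESFYY
s g001.chr3 296568 49 + 1000000 --F-AQY-MGJCHNRDRKKQ-VAECAKYDDDYHTNYE-TPKVWKJNNKGNYACPJ
s g002.chr3 269234 51 - 1000000 KGVNNELYVADNL-GWRTFSALLQGHMTTWILTJSEQHJG-MWNFVPNDM--RTC

a score=125.3
s g000.chr1 360332 35 + 1000000 IGLPR-HWNEWH--GLGTELMWLI-K-VSVTSC-WGGQ-HAY
s g001.chr1 273659 39 + 1000000 QH-VLLNAKDWWNTHIYS--CRWQGHNECNIYFHCKIGASRT
s g002.chr1 920347 40 - 1000000 JERVLVLYSVRRFNICIHYH-DPE-CVRKAIHQKEEKVGRLE

a score=63.7
s g000.chr2 926312 26 - 1000000 PQEWQ-WFMHPVFHYSMFTWQWIKH-KC
s g001.chr2 273699 24 + 1000000 FHQRP-YEV-EYAGIMMDRCPL-SWAW-
s g002.chr2 192337 25 - 1000000 ICPLWWI-SCDH-IYNNGVFDDS-QHLN

a score=-15.5
s g000.chr3 629922 18 + 1000000 NM-PGVFLLEQRDE-SCR-HJ
s g001.chr3 571471 19 + 1000000 KGDYG-AAIAKTCRDEGPSL-
s g002.chr3 350956 20 - 1000000 DVWNRTFAPASISQ-VPCQFC

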