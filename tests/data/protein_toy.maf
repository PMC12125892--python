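##maf version=1
a score=10.0
s sp1.prot1 0 4 + 100 MKV-L
s sp2.prot1 0 5 + 100 MKVAL

a
s sp1.prot1 4 3 + 100 WYJ
s sp2.prot1 5 3 + 100 WYA
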