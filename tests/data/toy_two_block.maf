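##maf version=1 scoring=toy
# hand-written two-block toy alignment
a score=23.0
s hg38.chr1 0 4 + 1000 AC-GT
s mm10.chr2 10 4 + 2000 ACG-T
q mm10.chr2 99F-1

a
s hg38.chr1 4 5 + 1000 ACGTN
s rn6.chr3 0 5 - 500 acgta
i rn6.chr3 N 0 C 0
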