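# ID83 indel channel schema.
# Naming: size:Del|Ins:context:bin
#   1:Del:B:k  1-bp deletion of base B (strand-collapsed A/T->T, C/G->C);
#              k = identical bases remaining adjacent after deletion, capped at 5.
#   1:Ins:B:k  1-bp insertion; k = existing homopolymer length of the inserted
#              base at the site, capped at 5.
#   n:Del:R:k  deletion of an n-bp unit (n=5 means 5+); k = additional intact
#              copies of the unit remaining in the reference, capped at 5.
#   n:Ins:R:k  insertion of an n-bp unit; k = existing copies at the site.
#   n:Del:M:k  deletion of length n with no remaining repeat copy but with
#              microhomology of length k to the flank (k=5 means 5+).
1:Del:C:0
1:Del:C:1
1:Del:C:2
1:Del:C:3
1:Del:C:4
1:Del:C:5
1:Del:T:0
1:Del:T:1
1:Del:T:2
1:Del:T:3
1:Del:T:4
1:Del:T:5
1:Ins:C:0
1:Ins:C:1
1:Ins:C:2
1:Ins:C:3
1:Ins:C:4
1:Ins:C:5
1:Ins:T:0
1:Ins:T:1
1:Ins:T:2
1:Ins:T:3
1:Ins:T:4
1:Ins:T:5
2:Del:R:0
2:Del:R:1
2:Del:R:2
2:Del:R:3
2:Del:R:4
2:Del:R:5
3:Del:R:0
3:Del:R:1
3:Del:R:2
3:Del:R:3
3:Del:R:4
3:Del:R:5
4:Del:R:0
4:Del:R:1
4:Del:R:2
4:Del:R:3
4:Del:R:4
4:Del:R:5
5:Del:R:0
5:Del:R:1
5:Del:R:2
5:Del:R:3
5:Del:R:4
5:Del:R:5
2:Ins:R:0
2:Ins:R:1
2:Ins:R:2
2:Ins:R:3
2:Ins:R:4
2:Ins:R:5
3:Ins:R:0
3:Ins:R:1
3:Ins:R:2
3:Ins:R:3
3:Ins:R:4
3:Ins:R:5
4:Ins:R:0
4:Ins:R:1
4:Ins:R:2
4:Ins:R:3
4:Ins:R:4
4:Ins:R:5
5:Ins:R:0
5:Ins:R:1
5:Ins:R:2
5:Ins:R:3
5:Ins:R:4
5:Ins:R:5
2:Del:M:1
3:Del:M:1
3:Del:M:2
4:Del:M:1
4:Del:M:2
4:Del:M:3
5:Del:M:1
5:Del:M:2
5:Del:M:3
5:Del:M:4
5:Del:M:5
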