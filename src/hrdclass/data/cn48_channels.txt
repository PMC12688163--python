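# CN48 allele-specific copy-number channel schema (state:total-CN class:size).
# States: homdel (total=0), LOH (minor=0, total>=1), het (minor>=1).
0:homdel:0-100kb
0:homdel:100kb-1Mb
0:homdel:>1Mb
1:LOH:0-100kb
1:LOH:100kb-1Mb
1:LOH:1Mb-10Mb
1:LOH:10Mb-40Mb
1:LOH:>40Mb
2:LOH:0-100kb
2:LOH:100kb-1Mb
2:LOH:1Mb-10Mb
2:LOH:10Mb-40Mb
2:LOH:>40Mb
3-4:LOH:0-100kb
3-4:LOH:100kb-1Mb
3-4:LOH:1Mb-10Mb
3-4:LOH:10Mb-40Mb
3-4:LOH:>40Mb
5-8:LOH:0-100kb
5-8:LOH:100kb-1Mb
5-8:LOH:1Mb-10Mb
5-8:LOH:10Mb-40Mb
5-8:LOH:>40Mb
9+:LOH:0-100kb
9+:LOH:100kb-1Mb
9+:LOH:1Mb-10Mb
9+:LOH:10Mb-40Mb
9+:LOH:>40Mb
2:het:0-100kb
2:het:100kb-1Mb
2:het:1Mb-10Mb
2:het:10Mb-40Mb
2:het:>40Mb
3-4:het:0-100kb
3-4:het:100kb-1Mb
3-4:het:1Mb-10Mb
3-4:het:10Mb-40Mb
3-4:het:>40Mb
5-8:het:0-100kb
5-8:het:100kb-1Mb
5-8:het:1Mb-10Mb
5-8:het:10Mb-40Mb
5-8:het:>40Mb
9+:het:0-100kb
9+:het:100kb-1Mb
9+:het:1Mb-10Mb
9+:het:10Mb-40Mb
9+:het:>40Mb
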