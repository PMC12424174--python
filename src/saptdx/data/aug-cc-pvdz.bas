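# aug-cc-pVDZ, standard published correlation-consistent values (Dunning and co-workers).
element H
S
     13.0100000    0.0196850
      1.9620000    0.1379770
      0.4446000    0.4781480
      0.1220000    0.5012400
S
      0.1220000    1.0000000
S
      0.0297400    1.0000000
P
      0.7270000    1.0000000
P
      0.1410000    1.0000000
element He
S
     38.3600000    0.0238090
      5.7700000    0.1548910
      1.2400000    0.4699870
S
      0.2976000    1.0000000
S
      0.0725500    1.0000000
P
      1.2750000    1.0000000
P
      0.2473000    1.0000000
element Be
S
   2940.0000000    0.0006800
    441.2000000    0.0052360
    100.5000000    0.0266060
     28.4300000    0.0999930
      9.1690000    0.2697020
      3.1960000    0.4514690
      1.1590000    0.2950740
      0.1811000    0.0125870
      0.0589000   -0.0037560
S
   2940.0000000   -0.0001230
    441.2000000   -0.0009660
    100.5000000   -0.0048310
     28.4300000   -0.0193140
      9.1690000   -0.0532800
      3.1960000   -0.1207230
      1.1590000   -0.1334350
      0.1811000    0.5307670
      0.0589000    0.5801170
S
      0.0589000    1.0000000
S
      0.0143900    1.0000000
P
      3.6190000    0.0291110
      0.7110000    0.1693650
      0.1951000    0.5134580
P
      0.0601800    1.0000000
P
      0.0140700    1.0000000
D
      0.2380000    1.0000000
D
      0.0720000    1.0000000
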