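# aug-cc-pVTZ, standard published correlation-consistent values (Dunning and co-workers).
# Format: "element <symbol>" then shell blocks "<L>" followed by "exponent coefficient"
# lines. Coefficients refer to normalized primitives; contracted functions are
# renormalized by the integral engine.
element H
S
     33.8700000    0.0060680
      5.0950000    0.0453080
      1.1590000    0.2028220
      0.3258000    0.5039030
      0.1027000    0.3834210
S
      0.3258000    1.0000000
S
      0.1027000    1.0000000
S
      0.0252600    1.0000000
P
      1.4070000    1.0000000
P
      0.3880000    1.0000000
P
      0.1020000    1.0000000
D
      1.0570000    1.0000000
D
      0.2470000    1.0000000
element He
S
    234.0000000    0.0025870
     35.1600000    0.0195330
      7.9890000    0.0909980
      2.2120000    0.2720500
      0.6669000    0.4780650
S
      0.6669000    1.0000000
S
      0.2089000    1.0000000
S
      0.0513800    1.0000000
P
      3.0440000    1.0000000
P
      0.7580000    1.0000000
P
      0.1993000    1.0000000
D
      1.9650000    1.0000000
D
      0.4592000    1.0000000
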