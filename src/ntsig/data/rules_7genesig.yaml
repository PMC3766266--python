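# 7-gene SD-rule signature: the 6-gene rules plus an ERBB3 tier that
# splits the r4-like profile into GNB-r4 (moderately high ERBB3) and
# GN-r4 (highest ERBB3).  RECONSTRUCTED defaults — see rules_6genesig.yaml.
# The ERBB3 rule is mandatory in every class (trivially so for the NB
# classes, where it is ANY), and min_rules = 6 of 7 encodes "ERBB3 rule
# plus at least 5 of the remaining 6".  The GNB-r4 ERBB3 rule carries an
# upper bound so the two nested UP tiers partition the z-axis.
signature_name: 7-GeneSig
min_rules: 6
classes: [NB-r1, NB-r2, NB-r3, GNB-r4, GN-r4]
rules:
  NB-r1:
    NTRK1: {direction: UP, threshold: 0.5, mandatory: true}
    PHOX2B: {direction: UP, threshold: 0.5}
    MYCN: {direction: DOWN, threshold: 0.5}
    BIRC5: {direction: DOWN, threshold: 0.5}
    ALK: {direction: DOWN, threshold: 0.5}
    CCND1: {direction: ANY}
    ERBB3: {direction: ANY, mandatory: true}
  NB-r2:
    ALK: {direction: UP, threshold: 0.5, mandatory: true}
    BIRC5: {direction: UP, threshold: 0.5}
    CCND1: {direction: UP, threshold: 0.5}
    PHOX2B: {direction: UP, threshold: 0.5}
    MYCN: {direction: DOWN, threshold: 0.5}
    NTRK1: {direction: DOWN, threshold: 0.5}
    ERBB3: {direction: ANY, mandatory: true}
  NB-r3:
    MYCN: {direction: UP, threshold: 0.5, mandatory: true}
    ALK: {direction: UP, threshold: 0.5}
    BIRC5: {direction: UP, threshold: 0.5}
    CCND1: {direction: UP, threshold: 0.5}
    NTRK1: {direction: DOWN, threshold: 0.5}
    PHOX2B: {direction: ANY}
    ERBB3: {direction: ANY, mandatory: true}
  GNB-r4:
    ALK: {direction: DOWN, threshold: 0.5, mandatory: true}
    BIRC5: {direction: DOWN, threshold: 0.5}
    CCND1: {direction: DOWN, threshold: 0.5}
    MYCN: {direction: DOWN, threshold: 0.5}
    NTRK1: {direction: DOWN, threshold: 0.5}
    PHOX2B: {direction: DOWN, threshold: 0.5}
    ERBB3: {direction: UP, threshold: 0.5, upper: 1.5, mandatory: true}
  GN-r4:
    ALK: {direction: DOWN, threshold: 0.5, mandatory: true}
    BIRC5: {direction: DOWN, threshold: 0.5}
    CCND1: {direction: DOWN, threshold: 0.5}
    MYCN: {direction: DOWN, threshold: 0.5}
    NTRK1: {direction: DOWN, threshold: 0.5}
    PHOX2B: {direction: DOWN, threshold: 0.5}
    ERBB3: {direction: UP, threshold: 1.5, mandatory: true}
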