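# 6-gene SD-rule signature over {ALK, BIRC5, CCND1, MYCN, NTRK1, PHOX2B}.
# RECONSTRUCTED defaults: the published per-gene SD cut-offs are not in the
# public full text, so directions and thresholds here are rebuilt from the
# narrative description of the subgroups and must not be cited as the
# published signature.  Thresholds are in SD units of the per-dataset
# z-score; a class qualifies when at least min_rules of its rules are met
# and every mandatory rule holds.
signature_name: 6-GeneSig
min_rules: 5
classes: [r1, r2, r3, r4]
rules:
  r1:
    NTRK1: {direction: UP, threshold: 0.5, mandatory: true}
    PHOX2B: {direction: UP, threshold: 0.5}
    MYCN: {direction: DOWN, threshold: 0.5}
    BIRC5: {direction: DOWN, threshold: 0.5}
    ALK: {direction: DOWN, threshold: 0.5}
    CCND1: {direction: ANY}
  r2:
    ALK: {direction: UP, threshold: 0.5, mandatory: true}
    BIRC5: {direction: UP, threshold: 0.5}
    CCND1: {direction: UP, threshold: 0.5}
    PHOX2B: {direction: UP, threshold: 0.5}
    MYCN: {direction: DOWN, threshold: 0.5}
    NTRK1: {direction: DOWN, threshold: 0.5}
  r3:
    MYCN: {direction: UP, threshold: 0.5, mandatory: true}
    ALK: {direction: UP, threshold: 0.5}
    BIRC5: {direction: UP, threshold: 0.5}
    CCND1: {direction: UP, threshold: 0.5}
    NTRK1: {direction: DOWN, threshold: 0.5}
    PHOX2B: {direction: ANY}
  r4:
    ALK: {direction: DOWN, threshold: 0.5, mandatory: true}
    BIRC5: {direction: DOWN, threshold: 0.5}
    CCND1: {direction: DOWN, threshold: 0.5}
    MYCN: {direction: DOWN, threshold: 0.5}
    NTRK1: {direction: DOWN, threshold: 0.5}
    PHOX2B: {direction: DOWN, threshold: 0.5}
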