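# Posture activation patterns, in matching precedence (first match wins).
# Atoms are sensor labels: seat 1-8, backrest a-d; an atom is true when
# that sensor's output exceeds the activation threshold.
- P1: "(3 or 7) and (4 or 8) and (a or d) and (b or c)"
- P5: "(3 or 7) and (2 or 8) and (a or c)"
- P6: "(3 or 7) and (2 or 8) and (b or d)"
- P4: "(3 or 4) and (a or b or c or d)"
- P2: "(3 or 7) and (2 or d)"
- P3: "(3 or 4)"
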