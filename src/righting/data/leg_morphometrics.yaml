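# Default two-segment leg morphometrics for the standardized nymph
# (L_body = 8.9 mm, whole-insect mass 28.4 mg).  segment_1 is the distal
# tibia+tarsus rod, segment_2 the proximal femur+trochanter+coxa rod.
# Values are a synthetic stand-in chosen to match the published gross
# facts for this species: legs long relative to the body (hindlegs
# longest, used for jumping) and carrying a large fraction of whole-body
# mass; see docs/methods.md for the derivation.
legs:
  L1:
    segment_1: {length_mm: 3.2, mass_mg: 0.60}
    segment_2: {length_mm: 2.6, mass_mg: 0.90}
  R1:
    segment_1: {length_mm: 3.2, mass_mg: 0.60}
    segment_2: {length_mm: 2.6, mass_mg: 0.90}
  L2:
    segment_1: {length_mm: 3.4, mass_mg: 0.65}
    segment_2: {length_mm: 2.8, mass_mg: 1.00}
  R2:
    segment_1: {length_mm: 3.4, mass_mg: 0.65}
    segment_2: {length_mm: 2.8, mass_mg: 1.00}
  L3:
    segment_1: {length_mm: 4.4, mass_mg: 0.95}
    segment_2: {length_mm: 3.4, mass_mg: 1.50}
  R3:
    segment_1: {length_mm: 4.4, mass_mg: 0.95}
    segment_2: {length_mm: 3.4, mass_mg: 1.50}
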