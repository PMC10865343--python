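# Six-parameter CNS desirability breakpoints (each parameter scored in [0, 1],
# total in [0, 6]).  Monotone-decreasing ramps are given as [favorable_edge,
# unfavorable_edge]; the TPSA hump as [zero_low, one_low, one_high, zero_high].
# Editable: absolute CNS MPO values depend on these constants.
mw: {kind: ramp_down, favorable: 360.0, unfavorable: 500.0}
clogp: {kind: ramp_down, favorable: 3.0, unfavorable: 5.0}
clogd: {kind: ramp_down, favorable: 2.0, unfavorable: 4.0}
tpsa: {kind: hump, zero_low: 20.0, one_low: 40.0, one_high: 90.0, zero_high: 120.0}
hbd: {kind: ramp_down, favorable: 0.5, unfavorable: 3.5}
pka_basic: {kind: ramp_down, favorable: 8.0, unfavorable: 10.0}
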