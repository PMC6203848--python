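# schematic reference mass model (Da); real end-group masses are
# chemistry-specific and should be edited in from instrument data
alpha_mass: 100.0
omega_mass: 50.0
delta_left: 1.0
delta_right: 2.0
adduct_mass: 22.98922   # sodium cationization
charge: 1
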