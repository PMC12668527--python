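"""Physical constants (SI, CODATA values rounded to double precision)."""

C0 = 299_792_458.0          # speed of light in vacuum, m/s
MU0 = 1.25663706212e-6      # vacuum permeability, H/m
EPS0 = 8.8541878128e-12     # vacuum permittivity, F/m
ETA0 = (MU0 / EPS0) ** 0.5  # vacuum wave impedance, ohm (~376.73)
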