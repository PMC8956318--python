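"""Unit conversions and clinically fixed constants.

The whole package computes in SI (kg, m, s); the conversions here are applied
only at the I/O boundary, where the transdermal-delivery literature uses
ng ml^-1 for plasma concentrations and ug cm^-2 h^-1 for skin fluxes.
"""

HOUR_S = 3600.0

#: kg m^-3 -> ng ml^-1 (1 kg m^-3 = 1 g L^-1 = 1e6 ng ml^-1)
KG_M3_TO_NG_ML = 1.0e6

#: kg m^-2 s^-1 -> ug cm^-2 h^-1
FLUX_SI_TO_UG_CM2_H = 3.6e8

#: Population-average analgesic floor for fentanyl plasma concentration.
THERAPEUTIC_MIN_NG_ML = 0.63
#: Population-average toxicity ceiling.
THERAPEUTIC_MAX_NG_ML = 2.0

#: Default minute-ventilation threshold used to report hypoventilation
#: duration (L min^-1). The normal-range floor is not standardized; every
#: hypoventilation output carries the threshold actually used.
HYPOVENTILATION_THRESHOLD_L_MIN = 12.0
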