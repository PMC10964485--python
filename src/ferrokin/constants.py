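"""Physical constants and molar masses used throughout the package.

All concentrations in this package are mg·L⁻¹, potentials mV vs SHE,
times hours, volumes litres, flows mL·h⁻¹ and biomass cells·mL⁻¹ unless a
function documents otherwise.
"""

#: Universal gas constant, J·mol⁻¹·K⁻¹.
GAS_CONSTANT = 8.314

#: Faraday constant, C·mol⁻¹.
FARADAY = 96485.0

#: Molar masses, g·mol⁻¹, of the species tracked in nutrient balances.
MOLAR_MASS = {
    "CO2": 44.01,
    "NH4+": 18.04,
    "K+": 39.10,
    "Mg2+": 24.31,
    "SO4 2-": 96.06,
    "PO4 3-": 94.97,
    "Fe": 55.845,
}

#: Default operating temperature, K (35 °C water-jacketed STRs).
DEFAULT_TEMPERATURE_K = 308.15
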