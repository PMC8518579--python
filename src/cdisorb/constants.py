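"""Physical constants used throughout the package (SI-based, 25 °C)."""

#: Faraday constant, C/mol (equivalently A·s/mol).
FARADAY = 96485.33212

#: Molar gas constant, J/(mol·K).
GAS_CONSTANT = 8.31446261815324

#: Working temperature, K. All equilibrium constants and the Davies
#: coefficient below assume 25 °C; there is no temperature dependence
#: elsewhere in the model.
TEMPERATURE = 298.15

#: R·T at 25 °C in kJ/mol; Boltzmann weights of molar interaction
#: energies are exp(-U / RT_KJ_MOL) with U in kJ/mol.
RT_KJ_MOL = GAS_CONSTANT * TEMPERATURE / 1000.0

#: Debye–Hückel/Davies A coefficient at 25 °C (log10 basis), (mol/L)^-1/2.
DAVIES_A = 0.509

#: Ion product of water at 25 °C, (mol/L)^2.
KW = 1.0e-14
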