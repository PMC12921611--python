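"""Physical constants used throughout.

Lengths are Å, momentum transfer Å⁻¹, concentrations mg/mL, number
densities 1/mL, energies in units of k_B·T unless stated otherwise.
"""

#: Avogadro's number, 1/mol (CODATA exact).
N_A = 6.02214076e23

#: Boltzmann constant, J/K (CODATA exact); only needed when tabulated
#: potentials are supplied in absolute energy units.
K_B = 1.380649e-23

#: cm³ (= mL) per Å³.
ML_PER_A3 = 1e-24
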