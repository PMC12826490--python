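# Default kinetic parameter set for the GRK/EGFR perivitelline-space model.
# Units: lengths µm, times hr, surface concentrations mol µm^-2.
# Single values inside published ranges are package design choices and may be
# overridden from a user config file (see docs/methods.md for the rationale).
D: 3600.0            # ligand diffusivity, µm^2/hr (published range 36 - 360,000)
k_ec: 6.0            # complex internalization, 1/hr
k_on: 6.0e+23        # ligand-receptor binding, mol^-1 µm^3 / hr (range 6e22 - 6e25)
k_off: 6.0           # complex dissociation, 1/hr
R0: 6.7e-22          # free receptor density without ligand, mol/µm^2
k_er: 0.6            # ligand-independent receptor turnover, 1/hr (range 0.6 - 6)
alpha_rec: 0.7       # recycled fraction of internalized complexes (range 0.45 - 0.7)
alpha_deg: 0.3       # degraded fraction of internalized complexes (range 0.3 - 0.55)
k_rec: 2.3           # receptor recycling rate, 1/hr
k_deg: 2.3           # receptor degradation rate, 1/hr
k_d: 2.3             # dpERK degradation rate, 1/hr
V0: 2.0e-21          # reference ligand secretion flux, mol µm^-2 hr^-1
Q_r: 4.0e-22         # receptor production rate, mol µm^-2 hr^-1
k_s: 1.0             # dpERK production rate, 1/hr
H: 0.5               # perivitelline-space thickness, µm
gamma_STY: 5.0e+4    # calibrated Sprouty feedback strength (500 x 10^2)
gamma_KEK1: 1.0e+3   # calibrated Kekkon1 feedback strength (10 x 10^2)
K: null              # KEK1 normalization; null -> derived working-point scale
K_prime: null        # STY normalization; null -> derived working-point scale
k_STY: 1.0           # STY production from signal, 1/hr
k_dSTY: 2.3          # STY degradation, 1/hr
k_KEK1: 1.0          # KEK1 production from signal, 1/hr
k_dKEK1: 2.3         # KEK1 degradation, 1/hr
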