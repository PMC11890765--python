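"""Physical constants and unit conversions.

Internal canonical units are Angstrom (length), eV (energy), amu (mass).
All thresholds quoted in other unit systems are converted here, once.
"""

# CODATA 2018
KB_EV = 8.617333262e-5          # Boltzmann constant, eV / K
HARTREE_EV = 27.211386245988    # 1 E_h in eV
BOHR_ANGSTROM = 0.529177210903  # 1 a0 in Angstrom
EV_PER_J_MOL = 1.0 / 96485.33212331001  # 1 J/mol in eV (via Faraday constant)

# optimisation thresholds
FMAX_DEFAULT = 5e-3  # 5 meV/A: max per-atom force at convergence
PREOPT_ETOL_PER_ATOM = 1.0 * EV_PER_J_MOL  # 1 J mol^-1 atom^-1, in eV/atom

# outlier thresholds (converted to internal units where applicable)
FORCE_OUTLIER_EH_A0 = 0.5
FORCE_OUTLIER_EV_A = FORCE_OUTLIER_EH_A0 * HARTREE_EV / BOHR_ANGSTROM
FORMATION_ENERGY_OUTLIER_EV = 0.0
NORM_DISTANCE_OUTLIER = 0.5
BOND_ORDER_DISSOCIATION = 0.25
BOND_ORDER_CONSISTENCY_TOL = 0.5

# conformer deduplication
RMSD_DUPLICATE_A = 0.05

# normal-mode sampling
T_MAX_DEFAULT = 1000.0  # K
HESSIAN_STEP_A = 1e-3
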