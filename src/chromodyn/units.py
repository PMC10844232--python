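"""Physical constants and unit conversions.

Internal unit system for dynamics: energies in eV, lengths in Å, angles in
radians, time in fs, masses/moments of inertia in amu (·Å² for rotors).
Kinetic energy of a coordinate with mass m (amu or amu·Å²) and velocity v
(Å/fs or rad/fs) is ``0.5 * m * AMU_TO_EV * v**2`` eV.
"""

# 1 amu·Å²/fs² expressed in eV
AMU_TO_EV = 103.642696

# Reduced Planck constant, eV·fs
HBAR_EV_FS = 0.6582119569

# Boltzmann constant, eV/K
KB_EV = 8.617333262e-5

# 1 atomic unit of time in fs (used to map a.u. coupling thresholds)
AU_TIME_FS = 0.02418884254

DEG = 57.29577951308232  # degrees per radian
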