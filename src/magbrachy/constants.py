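"""Physical constants and elemental data used throughout the package.

Units follow medical-physics convention: energies in MeV, lengths in mm
at the transport level and cm at the cross-section level, mass thickness
in g/cm², densities in g/cm³.
"""

# Electron rest energy [MeV]
ELECTRON_MASS_MEV = 0.51099895

# Classical electron radius [cm]
R_ELECTRON_CM = 2.8179403262e-13

# Avogadro's number [1/mol]
N_AVOGADRO = 6.02214076e23

# Speed-of-light factor relating momentum to gyroradius:
# r[m] = p[GeV/c] / (0.299792458 * B[T])
GYRO_FACTOR = 0.299792458

# MeV/g -> Gy
MEV_PER_G_TO_GY = 1.602176634e-10

# Element table: symbol -> (Z, A [g/mol], I [eV])
# Mean excitation energies I follow the standard ICRU-37 recommendations.
ELEMENTS = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "Ar": (18, 39.948, 188.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
    "Ti": (22, 47.867, 233.0),
    "Fe": (26, 55.845, 286.0),
    "Ni": (28, 58.693, 311.0),
    "Zn": (30, 65.38, 330.0),
    "Ir": (77, 192.217, 757.0),
}
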