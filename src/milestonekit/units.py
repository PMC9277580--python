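"""Unit system and physical constants.

Internal units throughout the package: length in Å, time in ps, energy in
kcal/mol, mass in amu, temperature in K.  Rate constants are reported in the
conventional experimental units (s^-1 for unimolecular, M^-1 s^-1 for
bimolecular) via the conversion factors defined here.
"""

# Gas constant in kcal mol^-1 K^-1 (fixed so printed free energies are
# bit-stable across platforms).
GAS_CONSTANT_KCAL: float = 1.9872e-3

#: Standard concentration defining the free-energy reference state, mol/L.
STANDARD_CONCENTRATION_M: float = 1.0

#: Multiply a rate in ps^-1 by this to obtain s^-1.
PS_INV_TO_S_INV: float = 1.0e12

#: Multiply a time in ps by this to obtain seconds.
PS_TO_S: float = 1.0e-12

SECONDS_PER_HOUR: float = 3600.0

# 1 Å^3/ps (a volume flux per molecule) expressed in M^-1 s^-1:
# 1 Å^3 = 1e-27 L, 1/ps = 1e12/s, times Avogadro's number.
AVOGADRO: float = 6.02214076e23
A3_PER_PS_TO_M_INV_S_INV: float = 1.0e-27 * 1.0e12 * AVOGADRO  # = 6.02214076e8

# 1 kcal/mol expressed in amu Å^2 ps^-2 (the natural energy unit of the
# integrator): 1 kcal/mol = 4184 J/mol; 1 amu Å^2/ps^2 = 10 J/mol exactly
# enough for our purposes.
KCAL_PER_MOL_TO_AMU_A2_PS2: float = 418.4


def kT(temperature_K: float) -> float:
    """Thermal energy k_B*T in kcal/mol (per-mole convention)."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return GAS_CONSTANT_KCAL * temperature_K
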