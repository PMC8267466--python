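"""Physical constants and package-wide unit conventions.

Units are fixed across the package: lengths in nm, times in ps, energies
in kJ/mol, temperatures in K, charges in elementary charges (e).
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (molar gas constant R).
KB = 0.0083144621

#: Coulomb prefactor f = 1/(4 pi eps0), kJ mol^-1 nm e^-2.
COULOMB_FACTOR = 138.935458

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Default non-bonded cutoff, nm.
DEFAULT_CUTOFF = 1.2


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
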