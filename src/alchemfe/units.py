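"""Physical constants and unit conversions.

Working units throughout the package are kcal/mol for energies, Å for
lengths, and K for temperature.  Synthetic fixtures may instead run in
reduced (dimensionless) units by passing ``kB=1`` wherever a Boltzmann
constant is accepted.
"""

#: Boltzmann constant, kcal/(mol K).
KB_KCAL_MOL_K: float = 1.9872e-3

#: 1 eV in kcal/mol.
EV_TO_KCAL_MOL: float = 23.0605

#: Default minimum force-gradient at the softcore switching point,
#: 3 eV/Å² expressed in kcal/(mol Å²).
DEFAULT_GRADIENT_FLOOR: float = 3.0 * EV_TO_KCAL_MOL

#: 1 atm in kcal/(mol Å³), for the pV term of NPT reduced potentials.
ATM_TO_KCAL_MOL_A3: float = 1.4584e-5

#: ln(10) as used in the log P conversion, 2.303 to the precision the
#: partition-coefficient literature quotes it.
LN10: float = 2.303
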