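"""Physical constants and lineshape area coefficients.

All g-factor arithmetic in the package goes through these values so that a
single calibration point controls every reported g.
"""

import math

#: Planck constant, J·s (exact by SI definition, CODATA 2018).
PLANCK_H = 6.62607015e-34

#: Bohr magneton, J/T (CODATA 2018).
BOHR_MAGNETON = 9.2740100783e-24

#: g-factor of polycrystalline DPPH, the usual field/intensity standard.
G_DPPH = 2.0036

#: Default spin concentration of pure DPPH, spins/g.  One mole of DPPH
#: (M = 394.32 g/mol) carries one unpaired electron per molecule, so
#: N_A / M ≈ 1.53e21.  Real standards are calibrated; callers should
#: supply their own value and every report records the one used.
N_DPPH_DEFAULT = 1.53e21

#: Double-integral of the Gaussian derivative line with Ym = dBpp = 1:
#: A_G = e^{1/2}·sqrt(2π)/4 ≈ 1.0333 (area in units of Ym·dBpp²).
GAUSSIAN_AREA_COEFF = math.exp(0.5) * math.sqrt(2.0 * math.pi) / 4.0

#: Double-integral of the Lorentzian derivative line with Ym = dBpp = 1:
#: A_L = 2π/sqrt(3) ≈ 3.6276.
LORENTZIAN_AREA_COEFF = 2.0 * math.pi / math.sqrt(3.0)
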