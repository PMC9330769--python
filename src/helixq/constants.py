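"""Physical constants (CODATA 2018, via scipy) and package-wide defaults."""

from scipy import constants as _c

ELEMENTARY_CHARGE = _c.elementary_charge  # C
BOLTZMANN = _c.Boltzmann  # J/K
AVOGADRO = _c.Avogadro  # 1/mol
EPSILON_0 = _c.epsilon_0  # F/m

#: Relative permittivity of water at 298 K; fixed package-wide.
WATER_EPS_R = 78.5

#: Reference temperature (K).
T_REF = 298.0
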