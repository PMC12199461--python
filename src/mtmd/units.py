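"""Internal unit system: atomic mass units (u), Ångström, electron-volt.

All of the engine's equations are evaluated in this consistent system so
that no unit constants appear inside the equations of motion.  The derived
time unit is ``sqrt(u Å²/eV) ≈ 10.1805 fs``; femtoseconds are converted at
the interfaces only.
"""

import math

#: 1 internal time unit in femtoseconds, sqrt(1 u * 1 Å² / 1 eV).
_U_KG = 1.66053906660e-27
_EV_J = 1.602176634e-19
TIME_FS = math.sqrt(_U_KG * 1e-20 / _EV_J) * 1e15  # ≈ 10.180506 fs

#: Boltzmann constant in eV/K.
KB = 8.617333262e-5

#: 1 GPa expressed in eV/Å³.
GPA = 1e9 * 1e-30 / _EV_J  # ≈ 6.241509e-3


def fs_to_internal(t_fs: float) -> float:
    """Convert a time from femtoseconds to internal units."""
    return t_fs / TIME_FS


def internal_to_fs(t: float) -> float:
    """Convert a time from internal units to femtoseconds."""
    return t * TIME_FS


def freq_internal_to_per_ps(omega: float) -> float:
    """Convert an ordinary frequency from (internal time)⁻¹ to ps⁻¹."""
    return omega * 1e3 / TIME_FS
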