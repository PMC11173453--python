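"""Unit system and physical constants.

The package works throughout in the units customary for condensed-phase
free-energy simulation: energies in kcal/mol, lengths in Angstrom (Å), time
in femtoseconds, masses in amu (g/mol) and temperature in Kelvin.  All
constants below are derived at import time from SI values (CODATA, via
:mod:`scipy.constants`) rather than typed in by hand.

Conversion bookkeeping
----------------------
With the thermochemical calorie (4.184 J exactly) and amu = 1 g/mol, one
"mechanical" energy unit amu Å² fs⁻² equals 1/(4.184e-4) ≈ 2390.06 kcal/mol.
Equivalently, a force of 1 kcal/mol/Å accelerates a 1 amu particle by
4.184e-4 Å/fs².
"""

from scipy import constants as _si

#: Boltzmann constant, kcal mol^-1 K^-1.
KB: float = _si.R / (_si.calorie * 1000.0)

#: Reduced Planck constant, kcal fs mol^-1 (so that hbar*omega with omega in
#: rad/fs is an energy in kcal/mol).
HBAR: float = _si.hbar * _si.Avogadro / (_si.calorie * 1000.0) * 1e15

#: Acceleration produced by unit force on unit mass:
#: (kcal mol^-1 Å^-1) / amu  ->  Å fs^-2.
FORCE_TO_ACCEL: float = _si.calorie * 1e-4

#: Mechanical energy unit amu Å^2 fs^-2 expressed in kcal/mol.
MECH_TO_KCAL: float = 1.0 / FORCE_TO_ACCEL

#: Default simulation temperature (K); the thermostat setting used for every
#: headline run in this package.
ROOM_T: float = 298.0


def thermal_beta(temperature: float) -> float:
    """Inverse temperature 1/(kB T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
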