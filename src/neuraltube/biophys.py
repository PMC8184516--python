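"""Morphogen biophysics: protein size and translational diffusivity.

Two textbook-style estimates used to parametrise morphogen transport:

* the radius of gyration of a folded protein from its chain length,
  RG = 3 * N**(2/5) angstrom, and
* the He--Niemeyer correlation for translational diffusivity,
  D = 6.85e-15 * T / (eta * M**(1/3) * RG), stated for D in m^2/s with
  T in kelvin, eta in centipoise, M in kg/kmol and RG in angstrom.

The correlation's prefactor absorbs mixed units; evaluated literally with
the published WNT/SHH inputs it does *not* come out at the published
diffusivities of 150.7 and 133.4 um^2/s (see docs/methods.md), so this
module is a documented utility and the simulation defaults ship the
published D values directly in the parameter file.
"""

from __future__ import annotations

HE_NIEMEYER_PREFACTOR = 6.85e-15

#: chain lengths and molecular masses of the two morphogens
WNT_CHAIN_LENGTH = 370
SHH_CHAIN_LENGTH = 462
WNT_MASS_KDA = 40.98
SHH_MASS_KDA = 49.61
BODY_TEMPERATURE_K = 310.0
CYTOPLASM_VISCOSITY_CP = 0.75


def radius_of_gyration(n_residues: int) -> float:
    """Radius of gyration in angstrom from amino-acid chain length.

    RG = 3 * N**(2/5), the empirical scaling for folded proteins under
    physiological conditions.
    """
    if n_residues < 1:
        raise ValueError("chain length must be at least 1")
    return 3.0 * float(n_residues) ** 0.4


def diffusivity_estimate(
    T: float, eta: float, M: float, RG: float, prefactor: float = HE_NIEMEYER_PREFACTOR
) -> float:
    """Translational diffusivity from the He--Niemeyer correlation.

    Parameters
    ----------
    T : temperature in K
    eta : viscosity in cP
    M : molecular mass in kg/kmol (numerically: g/mol, i.e. Da)
    RG : radius of gyration in angstrom

    Returns
    -------
    D in m^2/s under the literal reading of the correlation (multiply by
    1e12 for um^2/s).  Pure function of its inputs; no hidden constants.
    """
    for name, v in (("T", T), ("eta", eta), ("M", M), ("RG", RG)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return prefactor * T / (eta * M ** (1.0 / 3.0) * RG)
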