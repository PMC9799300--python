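"""Unit conversions for mixing macroscopic rate constants with particle models.

Bimolecular rate constants are quoted in M^-1 min^-1 (per-molar, per-minute);
particle and compartment simulators work in cubic micrometres and molecule
counts.  1 um^3 = 1e-15 L, so a rate k [M^-1 min^-1] corresponds to a
volumetric rate k / (N_A * 1e-15) [um^3 min^-1] per molecule pair.
"""

AVOGADRO = 6.022e23
LITRES_PER_UM3 = 1e-15


def per_molar_to_um3(k_molar: float) -> float:
    """Convert a bimolecular rate from M^-1 min^-1 to um^3 min^-1 per pair."""
    return k_molar / (AVOGADRO * LITRES_PER_UM3)


def um3_to_per_molar(k_um3: float) -> float:
    """Convert a volumetric bimolecular rate from um^3 min^-1 to M^-1 min^-1."""
    return k_um3 * AVOGADRO * LITRES_PER_UM3


def sphere_volume_um3(radius_um: float) -> float:
    from math import pi

    return 4.0 / 3.0 * pi * radius_um**3


def pair_propensity(k_molar: float, volume_um3: float) -> float:
    """Per-pair association propensity (min^-1) in a well-mixed volume."""
    return per_molar_to_um3(k_molar) / volume_um3
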