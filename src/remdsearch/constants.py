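"""Physical constants in the AKMA unit system.

Energies are kcal·mol⁻¹, lengths Å, masses amu, charges elementary charges,
time fs, temperature K.  Velocities are therefore Å·fs⁻¹ and the kinetic
energy of an atom is ``0.5 * m * v**2 / ACC_FACTOR`` kcal·mol⁻¹.
"""

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
KB = 0.0019872041

#: Coulomb constant, kcal·mol⁻¹·Å·e⁻².
COULOMB = 332.0636

#: Conversion factor: 1 kcal·mol⁻¹·Å⁻¹ acting on 1 amu gives this many Å·fs⁻².
#: Equivalently, KE[kcal·mol⁻¹] = 0.5 * m[amu] * v²[Å²·fs⁻²] / ACC_FACTOR.
ACC_FACTOR = 4.184e-4

#: Avogadro-scaled particle density of liquid water at 298 K, molecules·Å⁻³.
WATER_NUMBER_DENSITY = 0.0334
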