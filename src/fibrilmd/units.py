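"""Unit system and physical constants.

The package works in the "real"-style unit system common to coarse-grained
biomolecular simulation: energies in kcal/mol, lengths in Å, time in fs and
masses in amu.  Stresses are therefore computed natively in kcal mol⁻¹ Å⁻³
and only converted to MPa at the reporting layer.
"""

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB = 1.987204259e-3

#: Conversion from (kcal mol⁻¹ Å⁻¹) / amu to acceleration in Å fs⁻².
#: 1 kcal/mol = 4.184e-4 amu Å² fs⁻².
KCAL_TO_AMU_A2_FS2 = 4.184e-4

#: 1 kcal mol⁻¹ Å⁻³ expressed in MPa (4184 J/mol / N_A / 1e-30 m³ / 1e6).
STRESS_TO_MPA = 6947.695

#: 1 Å/fs expressed in m/s.
ANGSTROM_PER_FS_TO_M_PER_S = 1.0e5
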