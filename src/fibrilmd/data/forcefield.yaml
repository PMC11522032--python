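# Coarse-grained force-field constants for the collagen fibril model.
# Units: lengths Å, stiffnesses kcal mol⁻¹ Å⁻², angle stiffness kcal mol⁻¹ rad⁻²,
# energies kcal mol⁻¹, mass amu.  version: increment when any constant changes.
version: 1
bonds:
  backbone:   {r0: 14.00, r1: 18.20, r_break: 21.00, k0: 17.13, k1: 97.66, z: 0.05}
  # reinforced chain extensions at the loaded fibril ends: same law, later rupture
  extension:  {r0: 14.00, r1: 18.20, r_break: 70.00, k0: 17.13, k1: 97.66, z: 0.05}
  divalent:   {r0: 18.52, r1: 20.52, r_break: 23.20, k0: 0.20,  k1: 41.84, z: 0.05}
  trivalent:  {r0: 18.52, r1: 22.12, r_break: 24.81, k0: 0.20,  k1: 54.60, z: 0.05}
  age:        {r0: 18.52, r1: 22.72, r_break: 31.72, k0: 0.10,  k1: 8.00,  z: 0.05}
angle:
  k_b: 14.98
  phi_min_deg: 170.0
  phi_max_deg: 180.0
pair:
  epsilon: 6.87
  sigma: 14.72
  lamda: 0.9
  cutoff_factor: 2.5
mass: 1358.7
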