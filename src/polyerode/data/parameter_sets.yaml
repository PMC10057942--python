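# Packaged kinetic parameter sets.  Internal units: metre / day / mol / kelvin,
# with units embedded in the key names.
#
# plga_literature: literature set for PLGA (37 C).
# plla_50c: PLLA set calibrated against accelerated rod degradation at 50 C;
#   this is the authoritative default parameterisation of the package.
parameter_sets:
  plga_literature:
    description: PLGA literature parameters, 37 C
    k1_per_day: 2.0e-3
    k2_m3_per_mol_day: 2.0e-3
    d0_m2_per_day: 1.0e-12
    ce0_mol_per_m3: 17300.0
    beta: 0.5
    alpha: 4.5
    temperature_K: 310.15
  plla_50c:
    description: PLLA calibrated at 50 C against rod GPC data
    k1_per_day: 2.0e-3
    k2_m3_per_mol_day: 1.2e-7
    d0_m2_per_day: 6.5e-12
    ce0_mol_per_m3: 17300.0
    beta: 0.5
    alpha: 4.5
    temperature_K: 323.15

# PLACEHOLDER activation energies (J/mol) for Arrhenius transfer between
# temperatures.  The values used in the original calibration are not public;
# these defaults are order-of-magnitude choices from typical polyester
# hydrolysis (k1, k2) and matrix-diffusion (D0) ranges and should be replaced
# with material-specific values when available.
activation_energies_J_per_mol:
  k1: 78000.0
  k2: 78000.0
  d0: 130000.0
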