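# Isotope registry for Cerenkov luminescence imaging.
#
# Users may add isotopes here (or point the loader at their own file).
# Fields:
#   half_life_min              physical half-life [minutes]
#   beta_endpoint_kev          beta spectrum endpoint (maximum kinetic energy) [keV]
#   mean_positron_range_mm     mean positron range in soft tissue [mm] (0 for beta-minus)
#   branching_fraction_beta    fraction of decays emitting the beta particle (0, 1]
#   daughter_z                 atomic number of the daughter nucleus (Coulomb correction)
#   beta_plus                  true for positron emitters
#
# Ga-68 uses the 68-minute half-life convention of the clinical literature
# (nuclear-data value 67.71 min); edit here if the tabulated value is preferred.
isotopes:
  Ga-68:
    half_life_min: 68.0
    beta_endpoint_kev: 1899.1
    mean_positron_range_mm: 2.8
    branching_fraction_beta: 0.889
    daughter_z: 30
    beta_plus: true
  F-18:
    half_life_min: 109.77
    beta_endpoint_kev: 633.5
    mean_positron_range_mm: 0.6
    branching_fraction_beta: 0.967
    daughter_z: 8
    beta_plus: true
  Zr-89:
    half_life_min: 4704.0
    beta_endpoint_kev: 902.0
    mean_positron_range_mm: 1.2
    branching_fraction_beta: 0.227
    daughter_z: 39
    beta_plus: true
  Y-90:
    half_life_min: 3846.0
    beta_endpoint_kev: 2280.0
    mean_positron_range_mm: 0.0
    branching_fraction_beta: 1.0
    daughter_z: 40
    beta_plus: false
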