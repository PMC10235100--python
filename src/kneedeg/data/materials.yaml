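# Default cartilage material parameter sets for the three constitutive models.
#
# Units: moduli in MPa, damping in MPa*s, permeability in m^4 N^-1 s^-1
# (converted to mm^4 N^-1 s^-1 at the load boundary), fractions dimensionless.
#
# FRPVE fluid fraction varies with normalized depth hz (1 = articular
# surface, 0 = bone interface): n_f(hz) = a - b*hz.  The TIPE model uses
# identical depth-wise zonal parameters for femoral and tibial cartilage.
frpve:
  femur:
    E_eps: 150.0      # strain-dependent fibril network modulus
    E_0: 0.92         # initial fibril network modulus
    E_m: 0.215        # non-fibrillar matrix modulus
    nu_m: 0.15        # non-fibrillar matrix Poisson ratio
    eta: 1062.0       # fibril damping coefficient
    k_0: 6.0e-15      # initial permeability
    n_f: {a: 0.8, b: 0.15}
  tibia:
    E_eps: 23.06
    E_0: 0.18
    E_m: 0.106
    nu_m: 0.15
    eta: 1062.0
    k_0: 18.0e-15
    n_f: {a: 0.8, b: 0.15}

htipe:
  femur:
    E_11: 60.0
    E_33: 3.0
    nu_12: 0.42
    nu_13: 1.9
    G_12: 5.25
    G_13: 7.9
    k: 6.0e-15
    n_f: 0.8
  tibia:
    E_11: 50.0
    E_33: 3.0
    nu_12: 0.42
    nu_13: 1.9
    G_12: 4.4
    G_13: 6.4
    k: 18.0e-15
    n_f: 0.8

tipe:
  # Zone fractions of total thickness, surface to bone:
  # superficial / middle / deep.
  zone_fractions: [0.15, 0.35, 0.50]
  superficial:
    E_11: 24.0
    E_33: 0.46
    nu_12: 0.42
    nu_13: 3.0
    G_12: 8.45
    G_13: 12.0
    k: 1.0e-15
    n_f: 0.8
  middle:
    E_11: 16.97
    E_33: 0.46
    nu_12: 0.42
    nu_13: 3.0
    G_12: 5.98
    G_13: 8.45
    k: 1.0e-15
    n_f: 0.8
  deep:
    E_11: 8.485
    E_33: 0.46
    nu_12: 0.42
    nu_13: 2.2
    G_12: 2.99
    G_13: 4.24
    k: 1.0e-15
    n_f: 0.8
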