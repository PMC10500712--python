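# Editable defaults for paratensor.
#
# Users may copy this file, edit it, and load it with
# paratensor.config.load_config(path).  All magnitudes below are ordinary
# literature-style parameterisations and are meant to be adjusted to the
# system at hand.

[isotopes]
# NMR-active isotope assumed for each element and its gyromagnetic ratio
# in rad s^-1 T^-1.  H -> 1H, N -> 15N, C -> 13C by default.

[isotopes.H]
isotope = "1H"
gamma = 267.52218744e6

[isotopes.N]
isotope = "15N"
gamma = -27.126180e6

[isotopes.C]
isotope = "13C"
gamma = 67.28284e6

[isotopes.F]
isotope = "19F"
gamma = 251.8148e6

[isotopes.P]
isotope = "31P"
gamma = 108.394e6

[csa]
# Default chemical-shift-anisotropy tensors for protein backbone spins.
# "pas" holds the traceless principal components (xx, yy, zz) in ppm;
# "beta_deg" tilts the zz principal axis away from the reference bond
# vector, within the local peptide plane.  Conventions:
#   H (amide proton): zz along the H->N bond
#   N (amide nitrogen): zz at beta from the N->H bond
#   C (carbonyl carbon): zz perpendicular to the O=C / C-N plane,
#       xx at beta from the C->O bond in the plane

[csa.H]
pas = [-5.8, 0.0, 5.8]
beta_deg = 8.0

[csa.N]
pas = [-62.8, -45.7, 108.5]
beta_deg = -17.0

[csa.C]
pas = [-86.5, 11.8, 74.7]
beta_deg = 38.0

[lanthanides]
# Trivalent lanthanide ion templates.  g and J follow Hund's rules for the
# free-ion ground term.  dchi_ax / dchi_rh are literature-sourced
# placeholder anisotropies (units of 1e-32 m^3) of the kind reported for
# lanthanide complexes of calbindin D9k; t1e is a representative electronic
# relaxation time in seconds.  These are starting points for calculations,
# not reference values.

[lanthanides.Ce]
g = 0.8571428571428571   # 6/7
J = 2.5
dchi_ax = 2.1
dchi_rh = 0.7
t1e = 1.0e-13

[lanthanides.Pr]
g = 0.8                  # 4/5
J = 4.0
dchi_ax = 3.4
dchi_rh = 2.1
t1e = 1.0e-13

[lanthanides.Nd]
g = 0.7272727272727273   # 8/11
J = 4.5
dchi_ax = 1.7
dchi_rh = 0.4
t1e = 1.0e-13

[lanthanides.Sm]
g = 0.2857142857142857   # 2/7
J = 2.5
dchi_ax = 0.2
dchi_rh = 0.1
t1e = 1.0e-13

[lanthanides.Eu]
g = 0.0                  # J = 0 ground term
J = 0.0
dchi_ax = -2.3
dchi_rh = -1.2
t1e = 1.0e-13

[lanthanides.Gd]
g = 2.0
J = 3.5
dchi_ax = 0.0
dchi_rh = 0.0
t1e = 1.0e-9

[lanthanides.Tb]
g = 1.5
J = 6.0
dchi_ax = 42.1
dchi_rh = 11.2
t1e = 2.5e-13

[lanthanides.Dy]
g = 1.3333333333333333   # 4/3
J = 7.5
dchi_ax = 34.7
dchi_rh = 20.3
t1e = 2.5e-13

[lanthanides.Ho]
g = 1.25                 # 5/4
J = 8.0
dchi_ax = 18.5
dchi_rh = 5.8
t1e = 2.0e-13

[lanthanides.Er]
g = 1.2                  # 6/5
J = 7.5
dchi_ax = -11.6
dchi_rh = -8.6
t1e = 2.0e-13

[lanthanides.Tm]
g = 1.1666666666666667   # 7/6
J = 6.0
dchi_ax = -21.9
dchi_rh = -20.1
t1e = 2.0e-13

[lanthanides.Yb]
g = 1.1428571428571428   # 8/7
J = 3.5
dchi_ax = -8.3
dchi_rh = -5.8
t1e = 1.5e-13
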