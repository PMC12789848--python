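# Fitted constants of the two-dimensional flux-footprint parameterization
# (Kljun et al. 2015, Geosci. Model Dev. 8, 3695-3713), derived from a
# backward Lagrangian stochastic particle dispersion model. The crosswind-
# integrated footprint in scaled coordinates is
#   F*(X*) = a (X* - d)^b exp(-c / (X* - d))
# and the scaled crosswind spread is
#   sigma_y* = ac sqrt(bc X*^2 / (1 + cc X*)).
a: 1.4524
b: -1.9914
c: 1.4622
d: 0.1359
ac: 2.17
bc: 1.66
cc: 20.0
# Neutral Obukhov-length limit beyond which stability corrections vanish (m)
oln: 5000.0
# von Karman constant
k: 0.4
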