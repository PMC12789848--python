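# Default atmospheric perturbation parameters.
#
# CO2 impulse response: five non-interacting pools, one quasi-permanent
# (infinite lifetime) plus four decaying pools. Coefficients are the classic
# five-term fit of the Bern carbon-cycle impulse response (Joos et al.
# lineage, as used in wetland radiative-forcing models, e.g. Neubauer &
# Megonigal 2015; Arias-Ortiz et al. 2021). Fractions sum to 1.
# (last fraction adjusted by -1e-6 from the published rounding so the
# fractions sum to exactly 1)
co2_pool_fractions: [0.175602, 0.137467, 0.185762, 0.242302, 0.258867]
co2_pool_lifetimes: [.inf, 421.093, 70.5965, 21.42165, 3.41537]   # years

# CH4: first-order decay with a perturbation lifetime of 12.4 years
# (IPCC AR5); decayed CH4 carbon is oxidized to CO2 with yield 1.
ch4_lifetime: 12.4          # years
ch4_oxidation_yield: 1.0    # fraction of decayed CH4-C re-emitted as CO2

# Radiative efficiencies per kg of gas in the atmosphere (W m-2 kg-1),
# derived from the IPCC AR5 per-ppb values (1.37e-5 W m-2 ppb-1 for CO2,
# 3.63e-4 W m-2 ppb-1 for CH4) and the molar mass of the atmosphere.
re_co2: 1.756e-15
re_ch4: 1.277e-13

# Multiplier on CH4 forcing for indirect effects (tropospheric ozone and
# stratospheric water vapour), IPCC AR5 convention.
ch4_indirect_multiplier: 1.65
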