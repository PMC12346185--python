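# Per-profile nutrient parameters for level-2 advice: the intake change
# required to lower CVD risk by 1% (delta_n, negative = reduce) and the
# optimal intake range [min, max] from the survival analysis over intake
# bins.  TFA has no known safe lower limit, so its min is 0.
schema_version: 1
delta_r: 0.01
units:
  energy_kj: kJ/day
  protein_g: g/day
  sfa_g: g/day
  tfa_g: g/day
  omega3_g: g/day
  omega6_g: g/day
profiles:
  health_conscious:
    energy_kj:  {delta_n: -307,  min: 8136,  max: 9360}
    protein_g:  {delta_n: -4.72, min: 64.74, max: 87.85}
    sfa_g:      {delta_n: -3.07, min: 13.41, max: 21.97}
    tfa_g:      {delta_n: -0.30, min: 0,     max: 1.42}
    omega3_g:   {delta_n: -0.31, min: 1.47,  max: 2.46}
    omega6_g:   {delta_n: -0.45, min: 7.98,  max: 13.08}
  omnivore:
    energy_kj:  {delta_n: -623,  min: 7486,  max: 9965}
    protein_g:  {delta_n: -3.19, min: 70.67, max: 92.96}
    sfa_g:      {delta_n: -2.79, min: 14.81, max: 23.71}
    tfa_g:      {delta_n: -0.33, min: 0,     max: 1.54}
    omega3_g:   {delta_n: -0.45, min: 1.49,  max: 2.42}
    omega6_g:   {delta_n: -0.42, min: 8.32,  max: 13.14}
  sweet_tooth:
    energy_kj:  {delta_n: -325,  min: 7252,  max: 9773}
    protein_g:  {delta_n: -3.48, min: 66.61, max: 90.47}
    sfa_g:      {delta_n: -3.06, min: 14.35, max: 23.37}
    tfa_g:      {delta_n: -0.37, min: 0,     max: 1.48}
    omega3_g:   {delta_n: -0.39, min: 1.41,  max: 2.33}
    omega6_g:   {delta_n: -0.42, min: 8.07,  max: 13.06}
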