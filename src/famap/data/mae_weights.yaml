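# Male-adult-equivalent (MAE) weight table.
#
# Household members are weighted by sex- and age-specific daily energy
# requirements relative to an adult male (2500 kcal per capita per day,
# weight 1.0). The values below are editable defaults in the style of
# published adult-equivalent scales, not a copy of any specific source;
# analyses are defined relative to the configured table.
reference_energy_kcal: 2500
bands:
  - {sex: any, age_min: 0,  age_max: 2,   weight: 0.30}
  - {sex: any, age_min: 3,  age_max: 4,   weight: 0.45}
  - {sex: any, age_min: 5,  age_max: 6,   weight: 0.55}
  - {sex: any, age_min: 7,  age_max: 9,   weight: 0.65}
  - {sex: any, age_min: 10, age_max: 14,  weight: 0.76}
  - {sex: male,   age_min: 15, age_max: 17,  weight: 0.90}
  - {sex: female, age_min: 15, age_max: 17,  weight: 0.76}
  - {sex: male,   age_min: 18, age_max: 59,  weight: 1.00}
  - {sex: female, age_min: 18, age_max: 59,  weight: 0.76}
  - {sex: male,   age_min: 60, age_max: 120, weight: 0.80}
  - {sex: female, age_min: 60, age_max: 120, weight: 0.66}
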