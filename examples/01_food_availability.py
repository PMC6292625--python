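"""Compute household food availability and livelihood contributions.

Builds three contrasting households by hand — a maize farmer who sells
part of the harvest, a cattle keeper, and a household living mostly off
off-farm wages — and derives the FA indicator (kcal per male adult
equivalent per day) and the share of FA each activity provides.
"""

from famap import (EnergyConversionTable, HouseholdSurveyRecord, MAEWeights,
                   ProductRecord, fa_table)

energy = EnergyConversionTable.default(staple_price=1.0)
weights = MAEWeights.default()

households = [
    HouseholdSurveyRecord(
        household_id="maize_farm", lon=32.5, lat=1.2,
        members=[(35, "male"), (33, "female"), (8, "male")],
        crop_records=[ProductRecord("maize", 1500, 600, 0.9),
                      ProductRecord("beans", 200, 0, 1.8)],
        land_area_ha=1.8),
    HouseholdSurveyRecord(
        household_id="cattle_keeper", lon=31.0, lat=2.4,
        members=[(50, "male"), (45, "female")],
        livestock_records=[ProductRecord("cattle", 250, 150, 2.5),
                           ProductRecord("milk", 800, 300, 0.6)],
        land_area_ha=3.0, herd_size_tlu=6.0),
    HouseholdSurveyRecord(
        household_id="wage_earner", lon=32.9, lat=0.3,
        members=[(28, "male")],
        crop_records=[ProductRecord("cassava", 300, 0, 0.4)],
        offfarm_income=1500.0, land_area_ha=0.4),
]

table = fa_table(households, energy, weights)
cols = ["household_id", "FA", "n_hh_mae", "act_crop", "act_livestock",
        "act_offfarm"]
print(table[cols].round(3).to_string(index=False))
print()
print("FA is the potential daily food energy per male adult equivalent;")
print("the act_* columns are the fractions of FA coming from crops,")
print("livestock and off-farm income (they sum to 1 for each household).")
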