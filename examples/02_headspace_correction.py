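"""Correct rumen-headspace spot samples for atmospheric-air contamination.

Samples drawn through the cannula are diluted by a variable fraction of
air (N2/O2).  Renormalising CO2 + CH4 + N2O to 100 vol% removes the
dilution exactly — whatever the contamination fraction was.
"""

import pandas as pd

import rumengas as rg

# one contaminated sample, hand-built: true composition diluted ~25% by air
raw = pd.DataFrame([{
    "cow_id": "cow1", "period": 1, "day": 1, "time_rel_feeding": 0.33,
    "co2": 60.0, "ch4": 15.0, "n2o": 0.006, "n2": 20.0, "o2": 4.994,
}])
corrected = rg.correct_air_contamination(raw)
print("raw sample:      CO2 60.0, CH4 15.0, N2O 0.006, N2 20.0, O2 5.0 vol%")
print("corrected:       CO2 {co2:.2f}, CH4 {ch4:.2f}, N2O {n2o:.5f} vol%".format(
    **corrected.iloc[0][["co2", "ch4", "n2o"]].to_dict()))
print("The three true rumen gases are rescaled to sum to 100 vol%.\n")

# a whole synthetic study: correction then per cow x period anchor ratios
study = rg.generate_study(rg.GeneratorParams(seed=42))
corrected = rg.correct_air_contamination(study["headspace"])
ratios = rg.anchor_ratios(corrected, method="time-weighted")
print(ratios.head(4).to_string(index=False))
print("\nEach N2O:CH4 ratio (L/L) is a time-weighted mean over the 16-point")
print("sampling day; it anchors N2O production to the chamber CH4 measurement.")
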