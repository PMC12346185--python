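# Localization table for feedback messages, keyed by (message id, profile
# variant).  Content strings are illustrative; the (id, variant) structure is
# the contract.  Level 1 (M1-M3) addresses food-group portions; level 2
# (M4-M7) addresses nutrient intake relative to the per-profile optimal range.
schema_version: 1
level1:
  M1:
    purpose: portion below reference — encourage increased consumption
    health_conscious: >-
      Your {food_group} intake is below the weekly reference. Try adding a
      grilled fish or lean poultry dish to a vegetable-rich meal you already
      enjoy; plant-based options such as legumes, tofu or quinoa also count.
    omnivore: >-
      Your {food_group} intake is below the weekly reference. Swap one red-meat
      meal for fish or poultry this week; plant-based proteins such as beans,
      tofu or quinoa are good alternatives too.
    sweet_tooth: >-
      Your {food_group} intake is below the weekly reference. A simple baked
      fish or chicken dish with a sweet glaze (for example honey-lime) can fit
      your taste; legumes, tofu or quinoa are plant-based alternatives.
  M2:
    purpose: portion at reference — maintenance encouragement
    health_conscious: "Your {food_group} intake matches the weekly reference - keep it up."
    omnivore: "Your {food_group} intake matches the weekly reference - keep it up."
    sweet_tooth: "Your {food_group} intake matches the weekly reference - keep it up."
  M3:
    purpose: portion above reference — encourage reduction of red/processed meat
    health_conscious: >-
      Your {food_group} intake is above the weekly reference. Replace a portion
      with a vegetable- or pulse-based main you already like.
    omnivore: >-
      Your {food_group} intake is above the weekly reference. Try swapping one
      portion for fish or skinless poultry.
    sweet_tooth: >-
      Your {food_group} intake is above the weekly reference. Try a lighter
      alternative such as a chicken and fruit salad instead of one portion.
level2:
  M4:
    purpose: low predicted CVD risk — general encouragement
    text: >-
      Your predicted cardiovascular risk is low. Keep up your current balance
      of energy, protein and fats.
  M5:
    purpose: high risk, intake below the optimal range — increase
    text: >-
      Your {nutrient} intake is below the optimal range for your profile.
      Aim to raise it toward {target} {units} per day.
  M6:
    purpose: high risk, intake within the optimal range — maintain
    text: >-
      Your {nutrient} intake is within the optimal range for your profile.
      Maintain your current level.
  M7:
    purpose: high risk, intake above the optimal range — decrease
    text: >-
      Your {nutrient} intake is above the optimal range for your profile.
      Aim to reduce it toward {target} {units} per day.
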