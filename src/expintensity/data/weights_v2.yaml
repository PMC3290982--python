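# AHS exposure-intensity algorithm, version 2 weighting factors
# (version-1 weights rescaled by 10, CR-glove reduction raised to 60%,
# boom and airblast weights raised, mix weight lowered relative to apply).
version: v2
mix_weights:
  did_not_mix: 0
  mix_lt50: 20
  mix_ge50: 50
repair_weights:
  "no": 0
  "yes": 20
apply_weights:
  air_blast: 150
  hand_spray: 90
  mist_blower_or_fogger: 90
  fog_or_mist_animals: 90
  greenhouse_sprayer: 90
  pour_fumigant_from_bucket: 90
  powder_duster: 90
  backpack_sprayer: 80
  dust_animals: 70
  pour_on_animals: 70
  garden_hose: 50
  hand_held_squeeze_or_squirt_bottle: 50
  watering_can: 50
  soil_injected_or_drilled: 40
  spray_over_rows: 40
  boom_on_tractor: 40
  broadcast_application: 40
  personally_applied_to_seed: 40
  banded_directed_spray_liquid: 30
  banded_application_granular: 20
  gas_canister: 20
  hang_pest_strips_in_barn: 20
  in_furrow: 20
  incorporated: 20
  inject_animals: 20
  seed_treatment: 20
  hand_spreader_or_push_spreader: 20
  planter_box: 20
  aerial: 10
ppe_rules:
  glove_cr_reduction: 0.60
  fabric_glove_reduction: 0.0
  other_item_rule: per_item
  per_item_reduction: 0.10
  per_item_cap: 0.30
  total_cap: 0.90
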