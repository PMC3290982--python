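# AHS exposure-intensity algorithm, version 1 weighting factors.
# Methods with no assigned version-1 weight carry the marker "unassigned".
version: v1
mix_weights:
  did_not_mix: 0
  mix_lt50: 3
  mix_ge50: 9
repair_weights:
  "no": 0
  "yes": 2
apply_weights:
  air_blast: 9
  hand_spray: 9
  mist_blower_or_fogger: 9
  fog_or_mist_animals: 9
  greenhouse_sprayer: 9
  pour_fumigant_from_bucket: 9
  powder_duster: 9
  backpack_sprayer: 8
  dust_animals: 7
  pour_on_animals: 7
  garden_hose: unassigned
  hand_held_squeeze_or_squirt_bottle: unassigned
  watering_can: unassigned
  soil_injected_or_drilled: 4
  spray_over_rows: 4
  boom_on_tractor: 3
  broadcast_application: 3
  personally_applied_to_seed: 2
  banded_directed_spray_liquid: 2
  banded_application_granular: 2
  gas_canister: 2
  hang_pest_strips_in_barn: 2
  in_furrow: 2
  incorporated: 2
  inject_animals: 2
  seed_treatment: 1
  hand_spreader_or_push_spreader: unassigned
  planter_box: unassigned
  aerial: 1
ppe_rules:
  glove_cr_reduction: 0.40
  fabric_glove_reduction: 0.20
  other_item_rule: categories
  categories:
    - items: [cartridge_respirator, tyvek_coveralls]
      reduction: 0.30
    - items: [face_shield, goggles, boots, apron, other]
      reduction: 0.20
  total_cap: 0.90
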