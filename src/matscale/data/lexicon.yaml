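# Normalization lexicon for free-text material descriptions.
#
# Applied in order: typo correction -> translation -> compound reduction
# -> synonym resolution -> vocabulary check.  Compound reduction keeps the
# head noun (explicit map first, then a last-token fallback), but leaves a
# phrase intact when the full phrase is a synonym key, so phrase-level
# synonyms like "frozen water" survive to the synonym step.  Anything that
# ends up outside the allowed vocabulary maps to "none".

typo_map:
  stonee: stone
  conrete: concrete
  sandd: sand
  marbel: marble
  watter: water
  woood: wood
  plasitc: plastic
  lether: leather
  cermic: ceramic

translation_map:
  stein: stone
  holz: wood
  wasser: water
  eis: ice
  rinde: bark
  glas: glass
  metall: metal
  pflanze: plant
  teppich: carpet
  marmor: marble
  leder: leather
  beton: concrete
  kunststoff: plastic
  stoff: fabric
  schnee: snow
  haut: skin
  papier: paper
  wachs: wax
  ton: clay
  fell: fur
  haar: hair
  federn: feathers

compound_map:
  scratched stone: stone
  desert sand: sand
  tree bark: bark
  sea water: water
  ocean water: water
  wood planks: wood
  stone wall: stone

synonym_map:
  frozen water: ice
  rock: stone
  timber: wood
  lumber: wood
  foliage: plant
  vegetation: plant
  leaves: plant
  cloth: fabric
  textile: fabric
  ocean: water
  sea: water
  pottery: ceramic
  porcelain: ceramic
  pelt: fur

# Non-material / unresolvable answers collapse to "none".
none_terms:
  - landscape
  - material
  - don't know
  - dont know
  - unknown
  - surface
  - texture
  - pattern
  - nothing
  - picture
  - image
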