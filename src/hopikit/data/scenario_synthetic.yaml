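# Synthetic default scenario: study conditions for the generator.
#
# Groups mirror the three free-listing samples (two student populations and
# a botanical-expert sample) plus the piloting and eye-tracking student
# samples, with their respective sample sizes.  Category attention weights
# w_g(c) are the groups' latent tendencies to recall each macro-category;
# expert attention is shifted towards plants and, within plants, towards
# specific taxa (specific_plant_boost).  Per-object prominence encodes how
# conspicuous each depicted object is; within the two species sets it uses
# the relative recall salience observed for those species, and the general
# plant terms carry large prominence because students overwhelmingly recall
# plants as scenery ("tree", "field").

groups:
  middle_school:
    n: 427
    mean_list_length: 8
    weights: {plant: 0.31, animal: 0.22, human_nonliving: 0.47}
    specific_plant_boost: 1.0
  naturparkschule:
    n: 388
    mean_list_length: 8
    weights: {plant: 0.30, animal: 0.20, human_nonliving: 0.50}
    specific_plant_boost: 1.0
  expert:
    n: 66
    mean_list_length: 12
    weights: {plant: 0.40, animal: 0.25, human_nonliving: 0.35}
    specific_plant_boost: 2.0
  pilot:
    n: 218
    mean_list_length: 8
    weights: {plant: 0.31, animal: 0.22, human_nonliving: 0.47}
    specific_plant_boost: 1.0
  eyetracking:
    n: 80
    mean_list_length: 8
    weights: {plant: 0.31, animal: 0.22, human_nonliving: 0.47}
    specific_plant_boost: 1.0

fixation:
  group: eyetracking
  exposure_s: 30.0
  fixations_per_second: 3.0
  duration_mean_s: 0.25
  duration_sigma: 0.6
  # animals need longer individual fixations to discriminate (small objects)
  category_duration_scale: {plant: 1.0, animal: 1.6, human_nonliving: 1.0}

identification:
  group: eyetracking
  # target per-taxon mean rubric scores; the generator converts each mean m
  # into rubric level probabilities via a Binomial(3, m/3) family
  target_means:
    wild strawberry: 3.00
    cherry tree: 3.00
    apple tree: 2.94
    pear tree: 2.91
    carrot: 2.89
    dandelion: 2.66
    common poppy: 2.40
    oak: 2.17
    stinging nettle: 1.90
    spruce: 1.66
    red squirrel: 3.00
    domestic cat: 3.00
    ladybird: 2.97
    roe deer: 2.95
    bumblebee: 2.92
    stag beetle: 2.00
    great tit: 1.43
    roman snail: 1.43
    peacock butterfly: 1.19
    alpine longhorn beetle: 0.30

# latent per-object prominence (positive; normalized within each
# macro-category before use)
prominence:
  # plants, general
  tree: 0.30
  field: 0.15
  forest: 0.12
  flower: 0.10
  grass: 0.06
  meadow: 0.05
  bush: 0.03
  hedge: 0.02
  # plants, specific
  cherry tree: 0.080
  apple tree: 0.078
  wild strawberry: 0.054
  carrot: 0.054
  stinging nettle: 0.051
  dandelion: 0.037
  common poppy: 0.029
  spruce: 0.012
  oak: 0.008
  pear tree: 0.005
  sunflower: 0.040
  birch: 0.010
  reed: 0.008
  water lily: 0.006
  moss: 0.004
  # animals
  domestic cat: 0.419
  red squirrel: 0.380
  roe deer: 0.347
  bumblebee: 0.314
  peacock butterfly: 0.194
  ladybird: 0.119
  roman snail: 0.113
  stag beetle: 0.033
  alpine longhorn beetle: 0.024
  great tit: 0.018
  bird: 0.050
  beetle: 0.020
  crow: 0.020
  hedgehog: 0.030
  rabbit: 0.030
  frog: 0.020
  dragonfly: 0.015
  earthworm: 0.005
  fox: 0.020
  stork: 0.015
  # human / non-living
  house: 0.25
  car: 0.20
  child: 0.15
  stream: 0.10
  beekeeper: 0.08
  stone: 0.05
  football: 0.05
  bench: 0.04
  fence: 0.03
  path: 0.03
  bridge: 0.025
  beehive: 0.02
  tractor: 0.06
  barn: 0.04
  well: 0.015
  ladder: 0.01
  basket: 0.01
  scarecrow: 0.02
  cloud: 0.04
  sun: 0.06
  mountain: 0.05
  pond: 0.03
  gate: 0.01
  wheelbarrow: 0.015
  kite: 0.01
  swing: 0.01
  boots: 0.005
  hat: 0.005
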