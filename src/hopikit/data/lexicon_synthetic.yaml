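# Synthetic standardization lexicon for the 71-object hidden-object scene.
# A best-effort reconstruction: the study's full raw-term dictionary is not
# published, so this file covers the depicted objects with a plausible set
# of synonyms.  Format: canonical -> {macro_category, specificity,
# collective, synonyms}.

# ---- plants: general growth-form / habitat terms ----
tree: {macro_category: plant, specificity: general, synonyms: [trees, big tree]}
field: {macro_category: plant, specificity: general, synonyms: [fields, cornfield]}
forest: {macro_category: plant, specificity: general, synonyms: [woods, wood]}
flower: {macro_category: plant, specificity: general, synonyms: [flowers, blossom]}
grass: {macro_category: plant, specificity: general, synonyms: [lawn]}
meadow: {macro_category: plant, specificity: general, synonyms: [pasture]}
bush: {macro_category: plant, specificity: general, synonyms: [shrub, bushes]}
hedge: {macro_category: plant, specificity: general, synonyms: [hedgerow]}

# ---- plants: specific taxa ----
cherry tree: {macro_category: plant, specificity: specific, synonyms: [cherry, cherries, sweet cherry]}
apple tree: {macro_category: plant, specificity: specific, synonyms: [apple, apples]}
wild strawberry: {macro_category: plant, specificity: specific, synonyms: [strawberry, strawberries]}
carrot: {macro_category: plant, specificity: specific, synonyms: [carrots]}
stinging nettle: {macro_category: plant, specificity: specific, synonyms: [nettle, nettles]}
dandelion: {macro_category: plant, specificity: specific, synonyms: [dandelions]}
common poppy: {macro_category: plant, specificity: specific, synonyms: [poppy, poppies]}
spruce: {macro_category: plant, specificity: specific, synonyms: [firs, fir, conifer, spruce tree]}
oak: {macro_category: plant, specificity: specific, synonyms: [oak tree]}
pear tree: {macro_category: plant, specificity: specific, synonyms: [pear, pears]}
sunflower: {macro_category: plant, specificity: specific, synonyms: [sunflowers]}
birch: {macro_category: plant, specificity: specific, synonyms: [birch tree]}
reed: {macro_category: plant, specificity: specific, synonyms: [reeds]}
water lily: {macro_category: plant, specificity: specific, synonyms: [waterlily]}
moss: {macro_category: plant, specificity: specific, synonyms: []}

# ---- animals (incl. the two collective categories) ----
bird: {macro_category: animal, collective: bird, synonyms: [birds, small bird]}
beetle: {macro_category: animal, collective: beetle, synonyms: [beetles, bug]}
domestic cat: {macro_category: animal, synonyms: [cat, kitty, house cat]}
red squirrel: {macro_category: animal, synonyms: [squirrel]}
roe deer: {macro_category: animal, synonyms: [deer]}
bumblebee: {macro_category: animal, synonyms: [bumble bee, bee]}
peacock butterfly: {macro_category: animal, synonyms: [butterfly]}
ladybird: {macro_category: animal, collective: beetle, synonyms: [ladybug, ladybirds]}
roman snail: {macro_category: animal, synonyms: [snail, snails]}
stag beetle: {macro_category: animal, collective: beetle, synonyms: []}
alpine longhorn beetle: {macro_category: animal, collective: beetle, synonyms: [blue beetle, longhorn beetle]}
great tit: {macro_category: animal, collective: bird, synonyms: [tit]}
crow: {macro_category: animal, collective: bird, synonyms: [black bird, raven]}
hedgehog: {macro_category: animal, synonyms: []}
rabbit: {macro_category: animal, synonyms: [hare, bunny]}
frog: {macro_category: animal, synonyms: [toad]}
dragonfly: {macro_category: animal, synonyms: []}
earthworm: {macro_category: animal, synonyms: [worm]}
fox: {macro_category: animal, synonyms: [red fox]}
stork: {macro_category: animal, collective: bird, synonyms: [white stork]}

# ---- human / non-living ----
house: {macro_category: human_nonliving, synonyms: [farmhouse, building]}
car: {macro_category: human_nonliving, synonyms: [auto]}
child: {macro_category: human_nonliving, synonyms: [kid, boy, girl]}
beekeeper: {macro_category: human_nonliving, synonyms: [bee keeper]}
stream: {macro_category: human_nonliving, synonyms: [creek, brook, river]}
stone: {macro_category: human_nonliving, synonyms: [rock, stones]}
football: {macro_category: human_nonliving, synonyms: [ball, soccer ball]}
bench: {macro_category: human_nonliving, synonyms: []}
fence: {macro_category: human_nonliving, synonyms: []}
path: {macro_category: human_nonliving, synonyms: [trail, way]}
bridge: {macro_category: human_nonliving, synonyms: []}
beehive: {macro_category: human_nonliving, synonyms: [hive, bee hive]}
tractor: {macro_category: human_nonliving, synonyms: []}
barn: {macro_category: human_nonliving, synonyms: [stable]}
well: {macro_category: human_nonliving, synonyms: []}
ladder: {macro_category: human_nonliving, synonyms: []}
basket: {macro_category: human_nonliving, synonyms: []}
scarecrow: {macro_category: human_nonliving, synonyms: []}
cloud: {macro_category: human_nonliving, synonyms: [clouds]}
sun: {macro_category: human_nonliving, synonyms: [sunshine]}
mountain: {macro_category: human_nonliving, synonyms: [mountains, hills]}
pond: {macro_category: human_nonliving, synonyms: [lake]}
gate: {macro_category: human_nonliving, synonyms: []}
wheelbarrow: {macro_category: human_nonliving, synonyms: []}
kite: {macro_category: human_nonliving, synonyms: []}
swing: {macro_category: human_nonliving, synonyms: []}
boots: {macro_category: human_nonliving, synonyms: [rubber boots]}
hat: {macro_category: human_nonliving, synonyms: [straw hat]}
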