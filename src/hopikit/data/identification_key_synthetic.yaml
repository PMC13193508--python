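# Synthetic identification answer key for the 20 target species (10 plants,
# 10 animals).  A best-effort reconstruction of an unpublished key: level3 =
# correct at species level, level2 = a different species within the correct
# order-or-higher group, level1 = correct order-or-higher group only.  The
# three sets are pairwise disjoint per taxon so rubric levels are
# unambiguous.

# ---- plants ----
wild strawberry:
  kingdom: plant
  level3: [wild strawberry, strawberry, fragaria vesca]
  level2: [raspberry, blackberry]
  level1: [berry, berry plant]
cherry tree:
  kingdom: plant
  level3: [cherry tree, cherry, prunus avium]
  level2: [plum tree, peach tree]
  level1: [fruit tree, tree]
apple tree:
  kingdom: plant
  level3: [apple tree, apple, malus domestica]
  level2: [pear tree, quince tree]
  level1: [fruit tree, tree]
pear tree:
  kingdom: plant
  level3: [pear tree, pear, pyrus communis]
  level2: [apple tree, quince tree]
  level1: [fruit tree, tree]
carrot:
  kingdom: plant
  level3: [carrot, daucus carota]
  level2: [parsnip, radish]
  level1: [vegetable, root vegetable]
dandelion:
  kingdom: plant
  level3: [dandelion, taraxacum officinale]
  level2: [sunflower, marigold]
  level1: [flower, wildflower]
common poppy:
  kingdom: plant
  level3: [common poppy, poppy, papaver rhoeas]
  level2: [tulip, anemone]
  level1: [flower, wildflower]
oak:
  kingdom: plant
  level3: [oak, oak tree, quercus robur]
  level2: [beech, maple]
  level1: [tree, deciduous tree]
stinging nettle:
  kingdom: plant
  level3: [stinging nettle, nettle, urtica dioica]
  level2: [deadnettle, mint]
  level1: [herb, weed]
spruce:
  kingdom: plant
  level3: [spruce, picea abies]
  level2: [fir tree, fir, pine, larch]
  level1: [conifer, evergreen]

# ---- animals ----
red squirrel:
  kingdom: animal
  level3: [red squirrel, squirrel, sciurus vulgaris]
  level2: [chipmunk, dormouse]
  level1: [rodent, mammal]
domestic cat:
  kingdom: animal
  level3: [domestic cat, cat, house cat]
  level2: [wildcat, lynx]
  level1: [mammal, predator]
ladybird:
  kingdom: animal
  level3: [ladybird, ladybug, seven spot ladybird, coccinella septempunctata]
  level2: [colorado beetle, leaf beetle]
  level1: [beetle, insect]
roe deer:
  kingdom: animal
  level3: [roe deer, deer, capreolus capreolus]
  level2: [red deer, fallow deer]
  level1: [mammal, ungulate]
bumblebee:
  kingdom: animal
  level3: [bumblebee, bumble bee, bombus]
  level2: [honeybee, hornet, wasp]
  level1: [bee, insect]
stag beetle:
  kingdom: animal
  level3: [stag beetle, lucanus cervus]
  level2: [rhinoceros beetle, longhorn beetle]
  level1: [beetle, insect]
great tit:
  kingdom: animal
  level3: [great tit, parus major]
  level2: [blue tit, sparrow]
  level1: [tit, bird, songbird]
roman snail:
  kingdom: animal
  level3: [roman snail, burgundy snail, helix pomatia]
  level2: [garden snail, slug]
  level1: [snail, mollusc]
peacock butterfly:
  kingdom: animal
  level3: [peacock butterfly, european peacock, aglais io]
  level2: [red admiral, small tortoiseshell]
  level1: [butterfly, insect]
alpine longhorn beetle:
  kingdom: animal
  level3: [alpine longhorn beetle, rosalia alpina]
  level2: [capricorn beetle, musk beetle]
  level1: [beetle, longhorn, insect]
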