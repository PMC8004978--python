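# Semi-quantitative terms and units removed during text normalization.
# One term per line; '#' starts a comment; matching is case-insensitive
# and applies to whole whitespace-delimited tokens after digit removal.
# English
slice
slices
piece
pieces
glass
glasses
cup
cups
bowl
bowls
plate
plates
portion
portions
half
quarter
small
big
large
little
some
of
a
an
the
with
and
gram
grams
g
kg
kilogram
kilograms
ml
millilitre
millilitres
milliliter
milliliters
dl
decilitre
decilitres
deciliter
deciliters
l
litre
litres
liter
liters
tablespoon
tablespoons
tbsp
teaspoon
teaspoons
tsp
handful
# French
tranche
tranches
morceau
morceaux
verre
verres
tasse
tasses
bol
bols
assiette
assiettes
demi
petit
petite
grand
grande
un
une
le
la
les
de
du
des
avec
et
gramme
grammes
cuillere
cuilleres
poignee
# German
scheibe
scheiben
stuck
stucke
glas
glaser
tasse
tassen
teller
halb
halbe
klein
kleine
gross
grosse
ein
eine
der
die
das
mit
und
gramm
loffel
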