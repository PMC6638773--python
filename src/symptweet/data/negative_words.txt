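abysmal
adverse
alarming
angry
rage
annoy
anxious
anxiety
attack
appalling
atrocious
awful
bad
broken
can't
not
cant
cannot
cold
collapse
crazy
cruel
cry
damage
damaging
depressed
depression
dirty
disease
disgust
distress
don't
dont
dreading
dreadful
dreary
fail
fear
scare
feeble
foul
fright
ghastly
grave
greed
grim
gross
grotesque
gruesome
guilty
hard
harm
hate
hideous
horrible
hostile
hurt
icky
ill
impossible
injure
injury
jealous
lose
lousy
messy
nasty
negative
never
no
nonsense
crap
shit
fuck
fukk
fuxk
nausea
nauseous
pain
reject
repulsive
repulse
revenge
revolting
rotten
rude
ruthless
sad
scary
severe
sick
slimy
smelly
sorry
sticky
stinky
stormy
stress
stuck
stupid
tense
terrible
terrifying
threaten
ugly
unfair
unhappy
unhealthy
unjust
unlucky
unpleasant
upset
unwanted
unwelcome
vile
wary
weary
wicked
worthless
wound
yell
yucky
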