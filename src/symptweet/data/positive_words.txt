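adore
adorable
accomplish
achievement
achieve
action
active
admire
adventure
agree
agreeable
amaze
amazing
angel
approve
attractive
awesome
beautiful
brilliant
bubbly
calm
celebrate
celebrating
charming
cheery
cheer
clean
congratulation
cool
cute
divine
earnest
easy
ecstasy
ecstatic
effective
efficient
effortless
elegant
enchanting
encouraging
energetic
energized
enthusiastic
enthusiasm
excellent
exciting
excited
fabulous
fair
familiar
famous
fantastic
fine
fit
fortunate
free
fresh
friend
fun
generous
genius
glowing
good
great
grin
handsome
happy
hilarious
hilarity
lmao
lol
rofl
haha
healthy
ideal
impressive
independent
intellectual
intelligent
inventive
joy
keen
laugh
legendary
light
lively
lovely
lucky
marvel
nice
okay
paradise
perfect
pleasant
popular
positive
powerful
pretty
progress
proud
quality
refresh
restore
right
smile
success
sunny
super
wealthy
money
cash
well
wonderful
wow
yes
yum
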