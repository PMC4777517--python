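# Demo list of common English four-letter words (one per line).
# Assembled by the package authors for offline word-game demonstrations;
# it is a small sample, not a competition dictionary.
ABLE
ACHE
ACID
AGED
ALSO
AREA
ARMY
AWAY
BABY
BACK
BAKE
BALD
BALL
BAND
BANE
BANK
BARE
BARK
BARN
BASE
BATH
BEAD
BEAM
BEAN
BEAR
BEAT
BEEN
BEER
BELL
BELT
BEND
BENT
BEST
BIKE
BILL
BIND
BIRD
BITE
BLOW
BLUE
BOAT
BOIL
BOLD
BOLT
BOMB
BOND
BONE
BOOK
BOOM
BOOT
BORE
BORN
BOTH
BOWL
BULK
BULL
BURN
BUSH
BUSY
CAFE
CAGE
CAKE
CALL
CALM
CAME
CAMP
CANE
CAPE
CARD
CARE
CART
CASE
CASH
CAST
CAVE
CELL
CENT
CHAT
CHIP
CITY
CLIP
CLUB
CLUE
COAL
COAT
CODE
COIL
COIN
COLD
COME
CONE
COOK
COOL
COPE
COPY
CORD
CORE
CORN
COST
COVE
CREW
CROP
CUBE
CURE
DARE
DARK
DATA
DATE
DAWN
DAYS
DEAD
DEAL
DEAN
DEAR
DEBT
DECK
DEED
DEEP
DEER
DENT
DESK
DIAL
DICE
DIED
DIET
DINE
DIRT
DISH
DIVE
DOCK
DOES
DOLL
DOME
DONE
DOOR
DOSE
DOTE
DOVE
DOWN
DRAG
DRAW
DREW
DROP
DRUM
DUAL
DUCK
DULL
DUNE
DUST
DUTY
EACH
EARN
EASE
EAST
EASY
EDGE
ELSE
EVEN
EVER
EVIL
EXIT
FACE
FACT
FADE
FAIL
FAIR
FAKE
FALL
FAME
FARE
FARM
FAST
FATE
FEAR
FEAT
FEED
FEEL
FEET
FELL
FELT
FILE
FILL
FILM
FIND
FINE
FIRE
FIRM
FISH
FIST
FIVE
FLAG
FLAT
FLEW
FLOW
FOAM
FOLD
FOLK
FOND
FOOD
FOOL
FOOT
FORD
FORE
FORK
FORM
FORT
FOUL
FOUR
FREE
FROG
FROM
FUEL
FULL
FUND
FURY
GAIN
GAME
GANG
GATE
GAVE
GAZE
GEAR
GENE
GIFT
GIRL
GIVE
GLAD
GLOW
GOAL
GOAT
GOES
GOLD
GOLF
GONE
GOOD
GORE
GOWN
GRAB
GRAY
GREW
GREY
GRID
GRIM
GRIP
GROW
GULF
HAIL
HAIR
HALF
HALL
HALT
HAND
HANG
HARD
HARE
HARM
HATE
HAVE
HAWK
HAZE
HEAD
HEAL
HEAP
HEAR
HEAT
HEEL
HELD
HELL
HELP
HERB
HERD
HERE
HERO
HIDE
HIGH
HIKE
HILL
HINT
HIRE
HOLD
HOLE
HOLY
HOME
HOOD
HOOK
HOPE
HORN
HOSE
HOST
HOUR
HUGE
HUNG
HUNT
HURT
ICON
IDEA
INCH
INTO
IRON
ITEM
JAIL
JAZZ
JOIN
JOKE
JUMP
JUNE
JURY
JUST
KEEN
KEEP
KEPT
KICK
KIND
KING
KITE
KNEE
KNEW
KNIT
KNOB
KNOT
KNOW
LACE
LACK
LAID
LAKE
LAMB
LAMP
LAND
LANE
LAST
LATE
LAWN
LAZY
LEAD
LEAF
LEAN
LEAP
LEFT
LEND
LENS
LENT
LESS
LIFE
LIFT
LIKE
LIMB
LIME
LINE
LINK
LION
LIST
LIVE
LOAD
LOAF
LOAN
LOCK
LOGO
LONE
LONG
LOOK
LOOP
LORD
LORE
LOSE
LOSS
LOST
LOUD
LOVE
LUCK
LUNG
LURE
MADE
MAIL
MAIN
MAKE
MALE
MALL
MANE
MANY
MARE
MARK
MASK
MASS
MATE
MAZE
MEAL
MEAN
MEAT
MEET
MELT
MEMO
MENU
MESH
MESS
MICE
MILD
MILE
MILK
MILL
MIND
MINE
MINT
MISS
MIST
MODE
MOLD
MOLE
MOOD
MOON
MORE
MOSS
MOST
MOTH
MOVE
MUCH
MUST
MUTE
MYTH
NAME
NAVY
NEAR
NEAT
NECK
NEED
NEST
NEWS
NEXT
NICE
NINE
NODE
NONE
NOON
NORM
NOSE
NOTE
OBEY
ODDS
ONCE
ONLY
ONTO
OPEN
ORAL
OVAL
OVEN
OVER
PACE
PACK
PAGE
PAID
PAIN
PAIR
PALE
PALM
PANE
PARK
PART
PASS
PAST
PATH
PAVE
PEAK
PEAR
PEAT
PEEL
PEER
PILE
PILL
PINE
PINK
PINT
PIPE
PITY
PLAN
PLAY
PLOT
PLUG
PLUS
POEM
POET
POLE
POLL
POND
POOL
POOR
PORE
PORK
PORT
POSE
POST
POUR
PRAY
PREY
PROP
PULL
PUMP
PURE
PUSH
QUIT
QUIZ
RACE
RACK
RAGE
RAID
RAIL
RAIN
RAKE
RANG
RANK
RARE
RATE
READ
REAL
REAR
RELY
RENT
REST
RICE
RICH
RIDE
RING
RIOT
RIPE
RISE
RISK
RITE
ROAD
ROAR
ROBE
ROCK
RODE
ROLE
ROLL
ROOF
ROOM
ROOT
ROPE
ROSE
RUDE
RUIN
RULE
RUSH
RUST
SAFE
SAGE
SAID
SAIL
SAKE
SALE
SALT
SAME
SAND
SANE
SAVE
SCAN
SEAL
SEAM
SEAT
SEED
SEEK
SEEM
SEEN
SELF
SELL
SEND
SENT
SHIP
SHOE
SHOP
SHOT
SHOW
SHUT
SICK
SIDE
SIGH
SIGN
SILK
SING
SINK
SITE
SIZE
SKIN
SKIP
SLID
SLIM
SLIP
SLOW
SNAP
SNOW
SOAP
SOAR
SOCK
SOFT
SOIL
SOLD
SOLE
SOME
SONG
SOON
SORE
SORT
SOUL
SOUP
SOUR
SPAN
SPIN
SPOT
STAR
STAY
STEM
STEP
STIR
STOP
SUCH
SUIT
SURE
SWAP
SWIM
TAIL
TAKE
TALE
TALK
TALL
TAME
TANK
TAPE
TASK
TEAM
TEAR
TELL
TEND
TENT
TERM
TEST
TEXT
THAN
THAT
THEM
THEN
THEY
THIN
THIS
TIDE
TIDY
TIED
TILE
TILL
TIME
TINY
TIRE
TOLD
TOLL
TONE
TOOK
TOOL
TORE
TORN
TOUR
TOWN
TRAP
TRAY
TREE
TRIM
TRIP
TRUE
TUBE
TUNE
TURN
TWIN
TYPE
UNIT
UPON
URGE
USED
USER
VAIN
VARY
VASE
VAST
VEIL
VEIN
VERY
VEST
VIEW
VINE
VOID
VOTE
WADE
WAGE
WAIT
WAKE
WALK
WALL
WAND
WANE
WANT
WARD
WARE
WARM
WARN
WASH
WAVE
WEAK
WEAR
WEED
WEEK
WELL
WENT
WERE
WEST
WHAT
WHEN
WHIP
WHOM
WIDE
WIFE
WILD
WILL
WIND
WINE
WING
WIPE
WIRE
WISE
WISH
WITH
WOKE
WOLF
WOOD
WOOL
WORD
WORE
WORK
WORM
WORN
WRAP
YARD
YARN
YEAR
ZERO
ZONE
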