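# Common English and clinical tokens treated as in-vocabulary so the
# misspelling corrector (which targets only symptom terms) never rewrites
# ordinary words that happen to sit one edit away from a symptom term.
a
about
admission
after
afebrile
ago
air
alert
all
allergies
also
am
an
and
any
appetite
appears
apparent
are
as
assessment
at
ate
back
baseline
be
became
because
bed
been
before
best
better
bilateral
blood
body
both
bough
breathe
brother
but
by
call
came
can
cannot
care
chart
checklist
chess
chest
child
chills
clear
clinic
cold
come
complaint
complains
complete
congestion
continue
control
couch
could
coworker
crest
current
daily
date
daughter
day
days
denies
denied
deny
denying
department
did
diet
discussed
dizziness
do
does
dose
down
dr
drink
due
during
each
eat
education
eight
emergency
evaluation
evening
events
every
exam
exertion
experience
family
father
feeling
feels
felt
fever
few
fight
fine
five
followup
follow
for
forgot
four
friend
from
gerd
get
given
go
good
grandfather
grandmother
had
has
have
he
headache
heart
her
here
high
him
his
home
hospital
hour
hours
husband
i
if
illness
improved
in
inhaler
instructed
instructions
intact
intermittent
is
it
its
just
labs
last
left
light
like
lightheadedness
list
low
lungs
made
may
medical
medication
medications
might
mild
moderate
month
months
morning
mother
much
nasal
nausea
new
night
no
normal
noted
notes
not
now
o
occasional
of
off
office
old
on
one
only
or
other
over
overnight
oxygen
pain
past
patient
per
persistent
physical
plan
please
pm
prescribed
present
presents
problem
problems
progress
pulse
put
questionnaire
range
rate
recent
refill
regarding
reports
rest
return
review
right
roommate
routine
runny
saturation
saw
schedule
seek
seen
see
severe
she
should
side
sight
since
sister
sleep
so
some
son
sore
sounds
stable
started
states
status
still
subjective
symptom
symptoms
systems
take
taking
test
than
that
the
their
then
therapy
there
these
they
this
though
three
throat
time
to
today
told
tolerated
tough
two
unremarkable
up
us
use
visit
vitals
vomiting
was
watch
water
week
weeks
well
went
were
what
when
which
while
wife
will
with
within
worse
worsens
worsening
year
years
yesterday
you
your
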