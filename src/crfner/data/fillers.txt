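patients
cells
study
results
activity
effect
effects
analysis
levels
response
clinical
significant
observed
treated
increased
decreased
reduced
induced
associated
assay
assays
vitro
vivo
human
mouse
model
models
method
methods
data
showed
shown
found
reported
suggest
suggests
evaluated
measured
determined
performed
obtained
compared
control
controls
group
groups
samples
tissue
plasma
serum
blood
cell
culture
cultures
viral
infection
infected
replication
therapy
therapeutic
efficacy
potent
potential
novel
role
mechanism
mechanisms
function
functions
interaction
interactions
structure
structural
concentration
concentrations
experiments
experimental
values
value
approach
present
presence
absence
addition
conditions
changes
important
specific
selective
selectivity
resistance
resistant
mutant
type
wild
screening
series
tested
testing
active
improved
markedly
strongly
weakly
moderate
relative
overall
respectively
furthermore
however
moreover
whereas
although
including
following
respective
several
various
different
similar
higher
lower
total
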