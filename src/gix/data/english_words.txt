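# Common-English word lexicon for the refinement spelling heuristic:
# a word found here (and containing no digits or internal capitals) is
# treated as descriptive rather than as a gene/protein name.
# General function words
a
an
and
the
of
in
on
at
to
for
from
with
without
by
as
is
are
was
were
be
been
being
has
have
had
not
no
nor
or
but
if
then
than
that
this
these
those
it
its
they
their
we
our
which
who
whose
when
where
while
during
under
over
between
among
through
into
onto
upon
about
above
below
after
before
both
each
every
all
any
some
most
more
less
least
few
several
many
much
other
another
same
such
only
also
very
highly
strongly
weakly
directly
indirectly
further
together
respectively
however
therefore
thus
whereas
although
because
since
against
within
across
per
via
# General nouns, verbs and adjectives
study
studies
result
results
analysis
analyses
method
methods
approach
data
figure
table
model
models
system
systems
level
levels
rate
rates
change
changes
increase
increased
increases
decrease
decreased
decreases
effect
effects
role
roles
function
functions
functional
structure
structural
process
processes
mechanism
mechanisms
pathway
pathways
network
networks
interaction
interactions
relationship
relationships
response
responses
condition
conditions
presence
absence
control
controls
controlled
controlling
required
requires
require
involved
involves
involve
observed
observe
measured
measure
detected
detect
identified
identify
described
describe
reported
report
shown
show
shows
showed
found
find
suggest
suggests
suggested
indicate
indicates
indicated
demonstrate
demonstrates
demonstrated
known
unknown
novel
new
important
significant
significantly
specific
specifically
similar
different
differential
common
rare
high
higher
low
lower
large
small
major
minor
early
late
first
second
third
final
initial
total
overall
# Biology-domain descriptive vocabulary
protein
proteins
gene
genes
factor
factors
product
products
enzyme
enzymes
cell
cells
cellular
molecular
molecule
molecules
biology
biological
organism
organisms
bacterium
bacteria
bacterial
strain
strains
mutant
mutants
mutation
mutations
wild
type
types
genome
genomes
genomic
genetic
genetics
transcript
transcripts
transcription
transcriptional
translation
translational
expression
expressed
regulation
regulatory
regulated
induction
induced
repression
repressed
activation
activated
inhibition
inhibited
inhibitor
signal
signalling
signaling
receptor
receptors
kinase
kinases
phosphatase
ligand
ligands
substrate
substrates
domain
domains
motif
motifs
sequence
sequences
residue
residues
amino
acid
acids
peptide
peptides
polypeptide
ribosome
ribosomal
membrane
cytoplasm
cytoplasmic
nucleus
nuclear
chromosome
chromosomal
plasmid
plasmids
vector
vectors
clone
clones
cloned
cloning
culture
cultures
cultured
medium
media
growth
grown
phase
stationary
exponential
sporulation
spore
spores
germination
stress
heat
cold
shock
starvation
nutrient
nutrients
glucose
carbon
nitrogen
oxygen
iron
metal
metals
salt
salts
temperature
degrees
binding
bound
folding
folded
misfolding
unfolded
aggregation
assembly
chaperone
chaperones
synthesis
synthesized
degradation
degraded
stability
stable
unstable
homolog
homologous
ortholog
paralog
family
families
subunit
subunits
terminal
upstream
downstream
proximal
distal
region
regions
site
sites
locus
loci
operon
operons
promoter
promoters
terminator
enhancer
silencer
element
elements
box
boxes
codon
codons
intron
exon
splicing
polymerase
transcriptase
nuclease
protease
helicase
ligase
synthase
synthetase
reductase
oxidase
dehydrogenase
transferase
hydrolase
isomerase
permease
transporter
transport
secretion
secreted
export
import
uptake
efflux
antibiotic
antibiotics
resistance
resistant
susceptible
virulence
pathogen
pathogens
pathogenic
infection
host
hosts
immune
immunity
antibody
antibodies
antigen
assay
assays
experiment
experiments
experimental
replicate
replicates
sample
samples
extract
extracts
fraction
fractions
purified
purification
recombinant
fusion
tagged
labelled
labeled
probe
probes
primer
primers
amplified
amplification
hybridization
microarray
proteome
proteomic
transcriptome
metabolome
metabolism
metabolic
metabolite
metabolites
pathogenesis
phenotype
phenotypes
phenotypic
genotype
genotypes
viability
viable
lethal
essential
dispensable
deletion
insertion
substitution
duplication
fusion
truncated
overexpression
knockout
knockdown
silencing
reporter
luciferase
fluorescence
fluorescent
microscopy
spectrometry
chromatography
electrophoresis
blot
blotting
sequencing
alignment
annotation
database
databases
repository
literature
abstract
abstracts
publication
publications
paper
papers
suppressor
suppressors
activator
activators
repressor
repressors
regulator
regulators
effector
effectors
cofactor
cofactors
coactivator
corepressor
modulator
mediator
initiation
elongation
termination
consensus
affinity
specificity
kinetics
dynamics
equilibrium
concentration
concentrations
dose
doses
treatment
treatments
treated
untreated
incubated
incubation
overnight
harvested
centrifugation
supernatant
pellet
buffer
solution
mineral
density
optical
monitored
hour
hours
minute
minutes
day
days
survey
varied
variation
variations
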