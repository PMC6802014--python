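# Methods

`wolcall` re-implements, as a tested pipeline, the desk analysis behind an
MLST survey of *Wolbachia* endosymbionts in *Calligrapha* leaf beetles: allele
typing with double-infection deconvolution, strain grouping and recombinant
flagging on parsimony networks, permutation contingency tests of infection
against a nested mtDNA hierarchy, and fixed-tree ancestral-state
reconstruction.  This note documents the models, the parameter choices, the
numerical conventions, and what the synthetic data generator does and does
not emulate.

## MLST typing

Strains are characterised at the five standard *Wolbachia* MLST loci with
their canonical fragment sizes (gatB 369, coxA 402, hcpA 444, ftsZ 435,
fbpA 429 bp).  Coordinates are 0-based half-open on the forward strand of the
MLST reference orientation.

**Trimming.** A raw read is trimmed to the fragment window maximising
identity against the best-matching database allele (leftmost window on ties).
Windows below 80% identity are rejected as untypeable: that threshold is far
below within-supergroup allele divergence, so it only excludes off-target
amplicons, never a merely novel allele.

**Allele calling.** A clean fragment either matches a database allele exactly
or is novel (provisional single-letter ids continue the a, b, c, … series
within a locus; established numeric ids are never reissued).  A fragment with
IUPAC ambiguity codes is called a two-allele mixture only when, at *every*
position, the observed code equals the exact base union of one allele pair —
the signature of two superimposed Sanger traces.  Partial explanations are
refused (`unresolved`): permissive matching would silently absorb three-way
mixtures and chimeric components, and the one real failure mode this models
(an unreadable gatB polymorphism) is exactly the case that must surface.

**Chimera detection** uses a single-breakpoint, zero-mismatch model: a
fragment is mosaic iff it equals `prefix(x) + suffix(y)` for some ordered
allele pair and some breakpoint.  The reported breakpoint window is the
maximal interval of equally valid breakpoints; among pairs, smallest window
start wins, then lexicographic ids.  One breakpoint is the right model here
because the only mosaic this system shows is a single c/d recombinant gatB;
multi-breakpoint gene conversion would need evidence this data cannot give.

**Grouping.** Sequence types fall into three classes (wCallA/B/C) determined
by the gatB allele (a, b → A; c → B; d → C), with a caller-extensible mapping
for the chimeric gatB variant (→ B, following the mosaic's naming as a
wCallB1 variant).  The classes are *defined* by gatB even though wCallC5 sits
one allele change from wCallB1; that tension is deliberately surfaced by the
network loop report rather than resolved.

## Double-infection deconvolution

A doubly infected beetle shows, at each locus, the set union of its two
strains' alleles.  Deconvolution enumerates all ST pairs (anchor, partner)
whose locus-wise union reproduces the observation, where the anchor is any ST
already characterised (observed as a single infection or previously deduced)
and the partner is either known or a new profile within `max_new_dist` (= 1)
of a known ST — every deduced ST of the survey differs from a known one at a
single locus, and widening the radius would let one mixture mint arbitrarily
speculative strains.

Resolution preferences, in order:

1. pairs needing **no new ST**; among several, the pair whose members are
   most often attested as single infections wins (a dead tie is ambiguous);
2. otherwise the candidate minimising (distance of the new profile to the
   nearest known ST, then descending single-infection frequency of the
   anchor, then anchor id), minting the partner with provenance `deduced`.

Cohort-level classification iterates to a fixpoint: singles first (they
establish the empirical ST frequencies), then repeated passes in which
records resolvable without minting go first and each minting can unlock
further records.  Mixtures with an unreadable locus are resolved last and
only ever to an *ambiguous* state listing the known-ST pairs consistent with
the readable loci; such a record counts as a double-level infection (the
mixture proves two strains) but contributes to no per-ST tally.

**Known limitation.** Deconvolution from the seven observed STs alone
re-derives seven of the eight published deduced profiles exactly; the
wCallA5/wCallB4 complex admits a second, equally parsimonious resolution
(one alternative A-group profile in place of A5+B4) that locus-profile data
cannot exclude — the published resolution drew on which strains co-occur in
which populations.  Classification against the full packaged ST table (the
normal mode) is exact and deterministic.

Mosaic variants (chimeric allele at one locus, distance 1 from a known ST
otherwise) are named `<parent>r` with provenance `mosaic`; they are distinct
inventory entries but do not count toward the survey's sequence-type total,
matching how the source inventory counts 15 genotypes while listing the
mosaic separately.

## Networks, loops and nested clades

The minimum-spanning network over items (alleles, STs, haplotypes) retains
every tie-minimal connection: an edge belongs to the network iff its
endpoints are disconnected in the subgraph of strictly lighter edges (the
union of all minimum spanning trees).  Weight-1 pairs are therefore always
adjacent.  An optional connection limit drops heavier edges afterwards,
statistical-parsimony style; the default is unlimited for ST networks (at
most 5 allele changes) because the probability-of-parsimony computation that
would set a limit needs sequence-level information the ST profiles lack.

Loops are reported as a fundamental cycle basis (bounded output; an
exhaustive cycle census of a tie-rich network is exponential), and
*recombinant candidates* are the nodes on basis cycles touching two or more
strain groups.  With the allele-change metric the inter-group connections tie
at 3 steps in several places, so the candidate set is a superset of the three
rare recombinant STs the loops implicate; the analysis driver reports both
the full set and the three-ST core.

Nested-clade designs group network nodes one step inward from the tips
(anchors processed in decreasing eccentricity, lexicographic on ties;
stranded nodes become singleton clades; a tip-less component — a pure
cycle — nests as one clade), then iterate on the clade graph.  Once fully
nested, the partition is carried unchanged up to the requested level, so a
single node is trivially one clade at every level.  Published designs are
instead *imported* from assignment tables (labels kept verbatim, Unicode
hyphens normalised) and validated for strict nesting.

## Permutation contingency battery

Infection is encoded under the survey's coding schemes: infection level
(uninfected / single / double); strain-group combination ("A", "A+C", …);
specific genotype combination; each with and without the uninfected class;
level-prefixed variants separate e.g. single-A from double A+A hosts.
Ambiguous records keep their observed infection level but are excluded from
group/genotype schemes.

Each test cross-tabulates a host axis against an infection coding and
compares the Pearson X² statistic with its permutation distribution
(one margin permuted uniformly; add-one estimator
p = (1 + #{X*≥X})/(1 + n\_perm), which cannot be zero and is unbiased under
the null).  The default 9 999 permutations put the Monte-Carlo standard
error of a p-value near .05 at about 0.002.  Degenerate tables (one row or
one column after pruning) score 0 with p = 1 and are logged as skipped.

The battery tests the whole dataset (host axis: the highest hierarchy level
that still distinguishes clades) and every clade at every level (host axis:
the record's immediate child clade, one level down — the standard
nested-clade contingency frame).  Significance is starred at .05/.01/.001
without multiple-testing correction, as is conventional for these batteries;
a Bonferroni helper exists but is off by default.  Nuclear-marker (Wg)
follow-up tests run only within clades whose mtDNA test was significant,
unless asked for all.  Per-test seeds are spawned deterministically from the
battery seed, so reports are byte-stable.

## Ancestral-state reconstruction

Infection is a discrete character on a fixed, rooted host genealogy under
the symmetric k-state Markov model: closed-form transition probabilities,
uniform root prior (identical to the model's equilibrium), zero-length
branches clamped to 1e-9.  Tip ambiguity sets (a double infection as the set
of its two strain groups, an unreadable pair as full ambiguity over infected
states) enter as 0/1 partial likelihoods.  The single exchange rate is fitted
by bounded maximum likelihood on log10(rate) over [1e-6, 1e3]; with some
state compatible with every tip the ML rate is 0 and is returned directly.
Marginal posteriors come from the standard post-order partials plus
pre-order outside messages, with per-node rescaling against underflow.

Two codings mirror survey practice: `full_st` (one state per sequence type —
deduced ones included, whether or not ever seen alone — plus one state per
observed clean combination plus uninfected; the packaged cohort yields
15 + 15 + 1 = 31 states, with the mosaic variant folded into its parent) and
`grouped` ({uninfected, A, B, C}, doubles as two-group ambiguity sets).

This module deliberately conditions on an input tree and replaces the joint
Bayesian tree-plus-trait machinery such surveys use with ML rate fitting and
marginal reconstruction: the tree is an input artifact elsewhere in the
pipeline, and the reproducible surface at this scale is the qualitative
pattern (clade-specific modal ancestral infections), not posterior
percentages, which depend on tree priors, clock models and alignments this
package does not model.  A consequence worth knowing: under ambiguity coding
a strain that appears *only* inside double infections contributes little
independent signal, and reconstructed deep states follow the locally
dominant partner class.

## Synthetic data generator

The generator emulates the study design: a Kingman coalescent genealogy over
mtDNA haplotypes (exponential coalescence times, per-branch Poisson mutation
counts at 3 mutations per unit branch length, one private mutation forced
per tip so haplotypes are distinct); geographic regions as the maximal
clades under the deepest splits (range expansions leave geography confounded
with ancestry, which is the situation the association battery must detect);
a backbone strain inherited vertically with a per-branch loss probability;
and horizontal acquisition of the region-resident strain per sampled host.
Cytoplasmic-incompatibility exclusion is modelled as acquisition rejection —
a host never carries both a B- and a C-class strain — because only the
standing pattern (B/C parapatry, no co-occurrence) matters for testing
detection, not the incompatibility demography itself.

Defaults describe a survey of 500 specimens on 40 haplotypes in two regions,
vertical loss 0.05 per branch, horizontal acquisition 0.8 per host, resident
strains wCallB1 (west) and wCallC1 (east) over the packaged strain
inventory with wCallA1 as backbone.  Because loss acts on tree branches,
whole clades go uninfected together and the realised prevalence / double
fraction varies considerably between genealogies (roughly 0.85–1.0 and
0.3–0.8 across seeds) around a survey-like centre — the clade-correlated
pattern, not a fixed percentage, is the design target.  The generator's
nesting table is derived by cutting the true genealogy at increasing depth
quantiles (a simulated genealogy's tie-rich Poisson step distances make a
union-of-spanning-trees network too dense to nest; the tree is known, so the
clades come from it directly).

What the generator does **not** emulate: sequencing noise inside reads
(dropout and faint signals act on whole loci), paternal leakage, multiple
(>2) co-infections, mtDNA sequence evolution (haplotypes are labels with a
tree), titer differences between co-infecting strains, and opportunistic
geographic sampling.  Passing round-trip tests therefore show the pipeline
is exact on clean double-peak data and robust to locus-level dropout — not
that it would survive chromatogram-level artefacts.

All randomness flows from `numpy` generators seeded from the config seed;
emitted files are byte-identical across runs with the same config.

## Packaged survey dataset

The cross-tabulations of the source survey (sequence types, and specimen
counts per taxon × haplotype × infection) are embedded as structured tables
and expanded to a 506-record cohort.  Taxon identity follows the tables'
typographic coding; of the 83 beetles without a confirmed infection, 37 are
emitted with one faint-signal locus and 1 with two, exercising the
weak-signal path.  The real allele sequences are deposited in a public
nucleotide repository and are not embedded: the packaged alleles are
synthetic stand-ins, generated once from a fixed seed with the documented
pairwise-difference structure (pairwise-distinct alleles per locus, close
intra-class variants, and a gatB c/d pair differing at spread positions so
the single-breakpoint chimera is detectable).  The survey's itemised allele
counts (4+2+3+3+5 = 17) disagree with its own prose total of 18; the fixture
carries 17 and the discrepancy stays documented rather than resolved.
Likewise the prose prevalence (83.4%) disagrees with the tables' sum
(423/506 = 83.6%); reports print the recomputed value.

## Numerical conventions

Percentages display as one decimal, rounded half away from zero through the
decimal string representation (so 7.15% → 7.2, untroubled by binary
floats); raw fractions are preserved.  Permutation statistics compare with a
1e-12 slack so ties at the observed value count as at-least-as-extreme.
Profile and step distances are exact integers throughout.
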