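# wolcall

Multilocus sequence typing (MLST) and host-association analysis for
*Wolbachia* endosymbionts of *Calligrapha* leaf beetles.

Many insect species carry maternally inherited *Wolbachia* bacteria that can
manipulate host reproduction, sweep mitochondrial haplotypes to fixation,
and — in extreme cases — be blamed for transitions to all-female
(unisexual) reproduction.  Testing such hypotheses in a wild host requires a
chain of desk analyses downstream of Sanger sequencing: typing each beetle's
strain(s) at the five standard MLST loci (*gatB*, *coxA*, *hcpA*, *ftsZ*,
*fbpA*), splitting double infections read as superimposed chromatogram
peaks into their two component sequence types (STs), relating strain
diversity to the host's mtDNA genealogy, and asking which infections the
ancestors of each mtDNA lineage carried.  `wolcall` implements that chain as
a tested Python library with a thin CLI, packaged together with the
cross-tabulated specimen tables of a >500-beetle survey of two bisexual
*Calligrapha* species and their derived unisexual species.

## What is implemented

| module | contents |
|---|---|
| `wolcall.mlst` | allele databases (per-locus FASTA), read trimming, allele calling incl. IUPAC double-peak mixtures, ST profiles, Hamming profile distance, gatB-based strain grouping (wCallA/B/C), single-breakpoint chimera detection |
| `wolcall.coinfection` | per-specimen infection resolution; double-infection deconvolution by the subtraction rule (anchor on characterised STs, partner known or one locus from known); cohort fixpoint classification; ST inventory with observed/deduced/mosaic provenance |
| `wolcall.network` | minimum-spanning networks (union of all MSTs, optional connection limit), cycle-basis loop reports flagging recombinant-candidate STs, nested-clade construction and import/validation |
| `wolcall.association` | coding schemes for infection variables; Pearson X² with permutation p-values (add-one estimator); the nested-clade contingency battery; nuclear-marker (Wg) follow-up tests |
| `wolcall.ancestral` | symmetric k-state Markov (Mk) model on a fixed genealogy: pruning likelihood, ML rate fitting, marginal node posteriors, ambiguity-coded tips for double infections |
| `wolcall.simulate` | synthetic surveys with full ground truth: coalescent haplotype genealogy, regional lineages, vertical transmission with loss, region-resident horizontal acquisition, cytoplasmic-incompatibility exclusion of B+C co-infections |
| `wolcall.calligrapha` | the packaged survey dataset: 506 specimens, 15 STs + 1 mosaic variant, synthetic stand-in allele sequences |
| `wolcall.reporting`, `wolcall.cli` | prevalence tabulations on both denominators; `wolcall` command with `simulate / type / deconvolve / network / nest / assoc / asr / report` subcommands |

Numbered drivers under `analysis/` run the steps in order and write their
tables under `results/`; each prints what it found.

## The core statistics, briefly

**Deconvolution.** A doubly infected host shows the locus-wise allele union
of its two strains.  Given the set of characterised STs *S*, a mixture *M*
resolves to pairs (S₁, S₂) with `{S₁(l)} ∪ {S₂(l)} = M(l)` at every locus
*l*, S₁ ∈ *S*, and S₂ either in *S* or at profile distance 1 from some
member of *S*; preference goes to resolutions needing no new ST, then to
anchors most often seen as single infections.

**Association.** For a clade *c* of the nested mtDNA hierarchy, records are
cross-tabulated as (child clade of the record's haplotype) × (infection
coding), and X² = Σ (O−E)²/E is referred to its permutation distribution:
p = (1 + #{X²* ≥ X²}) / (1 + n_perm) with 9 999 permutations by default.

**Ancestral states.** Infection evolves on the genealogy under the
symmetric Mk model, P(same, t) = 1/k + (k−1)/k · e^(−kμt); the rate μ is
fitted by bounded ML and node posteriors come from the standard
post-order/pre-order sweep, with double infections entering as ambiguity
sets.

## Worked example

```bash
wolcall report --out report.tsv
```

prints nothing to stdout (results go to files, logs to stderr); the report
contains, among other lines:

```
specimens	506
uninfected	83	16.4%
infected	423	83.6%
single	120	28.4% of infected
double	303	71.6% of infected (incl. 1 with unresolved ST pair)
carrier	wCallA1	314	74.2% of infected	62.1% of all
carrier	wCallB1	151	35.7% of infected	29.8% of all
unisexual	uninfected	8/14	57.1%
unisexual	wCallA1 alone	3/14	21.4%
```

Reading it: of 506 beetles, 423 (83.6%) are infected; 303 of the infected
(71.6%) carry two strains at once, one of which could not be resolved to a
named ST pair because its *gatB* trace was unreadable.  The most widespread
strain, wCallA1, is in 74.2% of infected beetles.  The 14 beetles of the two
unisexual species are mostly uninfected (57.1%) or carry the ubiquitous
wCallA1 alone (21.4%) — the infection pattern that argues against
*Wolbachia* driving unisexuality in this genus.

The same numbers come from the library directly:

```python
from wolcall import calligrapha
from wolcall.coinfection import classify_cohort, count_sequence_types
from wolcall.reporting import tabulate_prevalence

records = calligrapha.load_cohort()
resolved, inventory = classify_cohort(
    records, calligrapha.st_table(),
    extra_gatb_groups=calligrapha.CHIMERIC_GATB_GROUPS,
    db=calligrapha.allele_database(),
)
count_sequence_types(inventory)          # 15
summary = tabulate_prevalence(resolved)
summary.pct_of_infected(summary.n_double_level)   # 71.6
```

## Scope notes

The package starts from called observations (allele-level tokens or
fragment sequences); chromatogram parsing, primer design, alignment and
phylogenetic tree search are upstream and out of scope.  Remote MLST
database lookups are replaced by a local allele database.  The packaged
allele sequences are synthetic stand-ins with the documented difference
structure (the survey's real alleles live in a public sequence repository);
see `docs/methods.md` for the models, parameter defaults and limitations.
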