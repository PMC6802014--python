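"""Packaged reference dataset: the *Calligrapha* / *Wolbachia* survey tables.

This module re-encodes, as loadable fixtures, the published cross-tabulation
of a 506-specimen survey of *Calligrapha* leaf beetles for *Wolbachia*
infection:

- the 15 sequence types (7 observed in single infections, 8 deduced from
  double infections) plus the ``wCallB1r`` mosaic variant with a chimeric
  *gatB* allele;
- the specimen table: for every (taxon, cox1 haplotype) combination the
  number of uninfected, singly and doubly infected beetles, with the
  co-infecting ST pair for doubles;
- a synthetic allele database.  The real allele sequences are deposited in a
  public repository and are not embedded here; the stand-ins are generated
  deterministically with the correct structure (pairwise-distinct alleles per
  locus, intra-group alleles closer than inter-group ones, and a *gatB*
  ``c``/``d`` pair differing at several spread positions so that the
  single-breakpoint ``c×d`` chimera carried by the mosaic individuals is
  detectable).

The survey itemises 4+2+3+3+5 = 17 alleles (its own prose total of 18 does
not match the itemised counts; the fixture uses 17, and the chimeric *gatB*
mosaic is registered separately and not counted as an allele of the survey).
"""

from __future__ import annotations

import numpy as np

from wolcall.coinfection import SpecimenRecord, StTable
from wolcall.mlst import (
    LOCI,
    LOCUS_NAMES,
    Allele,
    AlleleDatabase,
    MlstProfile,
    SequenceType,
)

# taxon labels
BIG = "C. multipunctata bigsbyana"
MUL = "C. multipunctata multipunctata"
PHI = "C. philadelphica"
SUT = "C. suturella"
VIC = "C. vicina"

#: The unisexual (all-female, hybrid-origin) species of the survey.
UNISEXUAL_TAXA = frozenset({SUT, VIC})

#: Group assignment for the chimeric gatB allele carried by wCallB1r.
CHIMERIC_GATB_GROUPS = {"r": "wCallB"}

# --------------------------------------------------------------------------
# Sequence types (ST table): id -> (gatB, coxA, hcpA, ftsZ, fbpA), provenance
# --------------------------------------------------------------------------

ST_DEFINITIONS: tuple[tuple[str, tuple[str, str, str, str, str], str, str], ...] = (
    ("wCallA1", ("a", "33", "42", "32", "36"), "wCallA", "observed"),
    ("wCallA2", ("b", "33", "42", "32", "36"), "wCallA", "observed"),
    ("wCallA3", ("b", "33", "42", "32", "d"), "wCallA", "observed"),
    ("wCallA4", ("a", "33", "42", "32", "e"), "wCallA", "observed"),
    ("wCallB1", ("c", "33", "c", "b", "b"), "wCallB", "observed"),
    ("wCallB2", ("c", "33", "c", "32", "b"), "wCallB", "observed"),
    ("wCallC2", ("d", "33", "b", "75", "c"), "wCallC", "observed"),
    ("wCallA5", ("a", "33", "42", "b", "36"), "wCallA", "deduced"),
    ("wCallA6", ("a", "33", "b", "32", "36"), "wCallA", "deduced"),
    ("wCallB3", ("c", "33", "b", "b", "b"), "wCallB", "deduced"),
    ("wCallB4", ("c", "33", "c", "75", "b"), "wCallB", "deduced"),
    ("wCallC1", ("d", "b", "b", "75", "c"), "wCallC", "deduced"),
    ("wCallC3", ("d", "b", "b", "75", "b"), "wCallC", "deduced"),
    ("wCallC4", ("d", "33", "b", "75", "b"), "wCallC", "deduced"),
    ("wCallC5", ("d", "33", "c", "b", "b"), "wCallC", "deduced"),
    ("wCallB1r", ("r", "33", "c", "b", "b"), "wCallB", "mosaic"),
)


def sequence_types(include_mosaic: bool = True) -> list[SequenceType]:
    """The published ST inventory (optionally without the mosaic variant)."""
    return [
        SequenceType(st_id, MlstProfile(alleles), group, provenance)
        for st_id, alleles, group, provenance in ST_DEFINITIONS
        if include_mosaic or provenance != "mosaic"
    ]


def observed_sequence_types() -> list[SequenceType]:
    """Only the 7 STs recognised directly from single infections."""
    return [st for st in sequence_types() if st.provenance == "observed"]


def st_table(include_mosaic: bool = True) -> StTable:
    return StTable(sequence_types(include_mosaic))


# --------------------------------------------------------------------------
# Specimen cross-tabulation
# --------------------------------------------------------------------------
# Each entry: (cox1 haplotype, number of beetles, taxon).

UNINFECTED_ENTRIES: tuple[tuple[str, int, str], ...] = (
    ("B1", 11, BIG), ("B6", 1, BIG), ("B14", 2, BIG), ("B15", 1, BIG),
    ("B18", 2, BIG), ("B27", 1, PHI), ("B28", 4, PHI), ("B29", 1, PHI),
    ("B31", 2, BIG), ("B32", 1, BIG), ("B33", 2, BIG), ("B35", 1, BIG),
    ("B46", 5, BIG), ("B47", 3, BIG), ("B48", 1, BIG), ("B57", 3, BIG),
    ("B58", 2, BIG), ("B59", 3, PHI), ("B69", 1, PHI), ("B73", 1, PHI),
    ("U1", 9, PHI), ("U2", 1, PHI), ("U3", 2, PHI), ("U3", 4, VIC),
    ("U4", 1, PHI), ("U5", 6, BIG), ("U5", 4, SUT), ("U7", 1, BIG),
    ("U8", 6, BIG), ("U13", 1, PHI),
)

SINGLE_INFECTION_ENTRIES: tuple[tuple[str, tuple[tuple[str, int, str], ...]], ...] = (
    ("wCallA1", (
        ("B1", 13, BIG), ("B12", 1, BIG), ("B18", 2, BIG), ("B38", 1, BIG),
        ("B45", 1, BIG), ("B46", 1, BIG), ("B49", 16, BIG), ("B54", 1, BIG),
        ("B63", 3, PHI), ("U1", 6, PHI), ("U3", 2, VIC), ("U5", 1, SUT),
        ("U9", 4, PHI), ("U10", 2, PHI), ("U11", 4, PHI), ("U12", 2, PHI),
        ("U13", 1, PHI),
    )),
    ("wCallA2", (("B1", 3, PHI), ("B7", 1, PHI), ("B14", 23, BIG))),
    ("wCallA3", (("B39", 1, BIG), ("B40", 1, BIG), ("B41", 1, BIG))),
    ("wCallA4", (("B1", 1, BIG),)),
    ("wCallB1", (
        ("B14", 2, BIG), ("B33", 8, MUL), ("B34", 2, MUL), ("B35", 2, MUL),
        ("B36", 2, MUL),
    )),
    ("wCallB2", (("B33", 1, MUL), ("B34", 2, MUL), ("B35", 2, MUL), ("B56", 1, MUL))),
    ("wCallC2", (("B59", 3, PHI), ("B68", 3, PHI))),
)

DOUBLE_INFECTION_ENTRIES: tuple[
    tuple[str, str, tuple[tuple[str, int, str], ...]], ...
] = (
    ("wCallA1", "wCallA6", (("B63", 1, PHI),)),
    ("wCallA1", "wCallB1", (
        ("B1", 1, PHI), ("B7", 1, PHI), ("B8", 1, BIG), ("B9", 4, BIG),
        ("B10", 1, BIG), ("B11", 4, BIG), ("B13", 1, BIG), ("B16", 2, BIG),
        ("B24", 10, BIG), ("B25", 1, BIG), ("B26", 1, PHI), ("B29", 13, PHI),
        ("B37", 1, BIG), ("B42", 8, BIG), ("B44", 1, BIG), ("B49", 25, BIG),
        ("B50", 2, BIG), ("B51", 1, BIG), ("B52", 1, BIG), ("B53", 10, BIG),
        ("B55", 1, BIG), ("B63", 1, PHI), ("B64", 1, PHI), ("U1", 6, PHI),
        ("U3", 1, VIC),
    )),
    ("wCallA1", "wCallB3", (("B49", 1, BIG),)),
    ("wCallA1", "wCallB4", (("B29", 1, PHI),)),
    ("wCallA1", "wCallC1", (
        ("B1", 68, BIG), ("B2", 1, BIG), ("B3", 1, BIG), ("B5", 1, BIG),
        ("B18", 40, BIG), ("B19", 1, BIG), ("B20", 1, BIG), ("B21", 1, BIG),
        ("U5", 1, SUT), ("U6", 1, SUT),
    )),
    ("wCallA1", "wCallC2", (
        ("B59", 15, PHI), ("B60", 1, PHI), ("B61", 1, PHI), ("B62", 3, PHI),
        ("B65", 3, PHI), ("B66", 1, PHI), ("B71", 1, PHI), ("B72", 1, PHI),
        ("U1", 1, PHI),
    )),
    ("wCallA1", "wCallC3", (("B1", 2, BIG), ("B18", 1, BIG))),
    ("wCallA1", "wCallC4", (("B65", 1, PHI),)),
    ("wCallA1", "wCallC5", (("B4", 1, BIG),)),
    ("wCallA2", "wCallB1", (
        ("B1", 4, PHI), ("B7", 1, PHI), ("B14", 6, BIG), ("B17", 5, BIG),
        ("B22", 1, PHI), ("B23", 1, PHI), ("B26", 2, PHI), ("B27", 7, PHI),
        ("B28", 7, PHI), ("B30", 2, PHI),
    )),
    ("wCallA2", "wCallC2", (("B71", 4, PHI),)),
    ("wCallA4", "wCallC1", (("B1", 1, BIG),)),
    ("wCallA5", "wCallB4", (("B29", 1, PHI), ("U1", 2, PHI))),
    ("wCallA5", "wCallC1", (("B1", 1, BIG),)),
    ("wCallA6", "wCallC2", (("B67", 3, PHI), ("B70", 1, PHI))),
    ("wCallA1", "wCallB1r", (("B42", 2, BIG), ("B43", 1, BIG))),
)

#: One individual whose gatB polymorphism could not be read; the readable
#: loci are consistent with a wCallB1 × wCallC1 double infection — the only
#: apparent co-occurrence of the B and C strain classes in the survey.
UNCERTAIN_DOUBLE_ENTRY: tuple[str, str, tuple[tuple[str, int, str], ...]] = (
    "wCallB1", "wCallC1", (("B18", 1, BIG),),
)

#: Breakdown of the 83 unamplified beetles: most never amplified any locus;
#: 37 gave a faint, unrepeatable band at one locus and 1 at two loci.
N_FAINT_ONE_LOCUS = 37
N_FAINT_TWO_LOCI = 1


# --------------------------------------------------------------------------
# Synthetic allele database
# --------------------------------------------------------------------------
# Each allele is the locus reference with substitutions at fixed positions;
# intra-group variants differ at 1 position, inter-group ones at several.

_ALLELE_SUBSTITUTIONS: dict[str, dict[str, tuple[int, ...]]] = {
    "gatB": {
        "a": (),
        "b": (10,),
        "c": (50, 150, 250, 350),
        "d": (50, 150, 250, 350, 60, 160, 260),
    },
    "coxA": {"33": (), "b": (20, 120)},
    "hcpA": {"42": (), "c": (30, 130, 230), "b": (30, 130, 230, 40)},
    "ftsZ": {"32": (), "b": (25, 125), "75": (25, 125, 225)},
    "fbpA": {
        "36": (), "d": (15,), "e": (45,),
        "b": (75, 175, 275), "c": (75, 175, 275, 85),
    },
}

_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}
_SEED = 20190907  # fixed: the fixture is a deterministic artifact


def _locus_reference(locus_index: int, length: int) -> str:
    rng = np.random.default_rng(_SEED + locus_index)
    return "".join(rng.choice(list("ACGT"), size=length))


def _substitute(reference: str, positions: tuple[int, ...]) -> str:
    seq = list(reference)
    for pos in positions:
        seq[pos] = _NEXT_BASE[seq[pos]]
    return "".join(seq)


def allele_database(include_chimeric: bool = True) -> AlleleDatabase:
    """The 17-allele synthetic database (plus the chimeric gatB mosaic).

    The chimeric allele ``gatB r`` is the single-breakpoint mosaic
    ``c[:200] + d[200:]`` carried by the wCallB1r individuals; it is
    registered with its parents so that typing can flag it, but it is not
    part of the survey's allele inventory.
    """
    db = AlleleDatabase(provenance="synthetic stand-in alleles, fixed seed")
    sequences: dict[str, dict[str, str]] = {}
    for index, locus in enumerate(LOCI):
        reference = _locus_reference(index, locus.fragment_length)
        sequences[locus.name] = {
            allele_id: _substitute(reference, positions)
            for allele_id, positions in _ALLELE_SUBSTITUTIONS[locus.name].items()
        }
        for allele_id, seq in sequences[locus.name].items():
            db.add(Allele(locus.name, allele_id, seq))
    if include_chimeric:
        c, d = sequences["gatB"]["c"], sequences["gatB"]["d"]
        db.add(Allele("gatB", "r", c[:200] + d[200:], chimera_of=("c", "d")))
    return db


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------


def _profile_of(st_id: str) -> MlstProfile:
    for sid, alleles, _, _ in ST_DEFINITIONS:
        if sid == st_id:
            return MlstProfile(alleles)
    raise KeyError(st_id)


def _single_tokens(profile: MlstProfile) -> dict[str, str]:
    return {locus: profile[locus] for locus in LOCUS_NAMES}


def _mixture_tokens(p1: MlstProfile, p2: MlstProfile) -> dict[str, str]:
    return {
        locus: "/".join(sorted({p1[locus], p2[locus]})) for locus in LOCUS_NAMES
    }


def load_cohort() -> list[SpecimenRecord]:
    """The full 506-specimen cohort with raw per-locus observation tokens.

    Specimens are numbered in table order (uninfected, then single
    infections, then double infections); the uncertain individual's gatB
    observation is the unreadable token ``"?"``.  Among the uninfected, 37
    specimens carry one faint-signal locus and 1 carries two, mirroring the
    survey's weak, unrepeatable PCR signals.
    """
    records: list[SpecimenRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"CAL{counter:04d}"

    faint_budget = [N_FAINT_TWO_LOCI, N_FAINT_ONE_LOCUS]  # two-locus first
    faint_locus = 0
    for haplotype, count, taxon in UNINFECTED_ENTRIES:
        for _ in range(count):
            observations = {locus: "" for locus in LOCUS_NAMES}
            if faint_budget[0] > 0:
                observations[LOCUS_NAMES[faint_locus % 5]] = "?low"
                observations[LOCUS_NAMES[(faint_locus + 1) % 5]] = "?low"
                faint_budget[0] -= 1
                faint_locus += 1
            elif faint_budget[1] > 0:
                observations[LOCUS_NAMES[faint_locus % 5]] = "?low"
                faint_budget[1] -= 1
                faint_locus += 1
            records.append(
                SpecimenRecord(new_id(), taxon, "", haplotype, observations=observations)
            )

    for st_id, entries in SINGLE_INFECTION_ENTRIES:
        tokens = _single_tokens(_profile_of(st_id))
        for haplotype, count, taxon in entries:
            for _ in range(count):
                records.append(
                    SpecimenRecord(new_id(), taxon, "", haplotype, observations=dict(tokens))
                )

    for st1, st2, entries in DOUBLE_INFECTION_ENTRIES:
        tokens = _mixture_tokens(_profile_of(st1), _profile_of(st2))
        for haplotype, count, taxon in entries:
            for _ in range(count):
                records.append(
                    SpecimenRecord(new_id(), taxon, "", haplotype, observations=dict(tokens))
                )

    st1, st2, entries = UNCERTAIN_DOUBLE_ENTRY
    tokens = _mixture_tokens(_profile_of(st1), _profile_of(st2))
    tokens["gatB"] = "?"
    for haplotype, count, taxon in entries:
        for _ in range(count):
            records.append(
                SpecimenRecord(new_id(), taxon, "", haplotype, observations=dict(tokens))
            )
    return records
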