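"""Resolving per-specimen MLST observations into infection states.

A specimen's observations at the five MLST loci are either empty (no
amplification), a clean single-allele profile, or a mixture with two alleles
superimposed at one or more loci (double Sanger peaks).  Mixtures arise from
double infections; this module deconvolves them into the two co-infecting
sequence types by the subtraction rule: anchor on an ST already characterised
in the sample, discount its alleles from the observed polymorphism, and check
that the remainder is itself a known ST or a new profile within a small
distance of one (the deduced genotypes of the survey each differ from a known
ST at a single locus).

Observation tokens (specimen-table dialect): ``"33"`` or ``"a"`` (single
allele), ``"a/b"`` (two-allele mixture), ``""`` (no amplification), ``"?"``
(unreadable polymorphism at the locus), ``"?low"`` (faint, unrepeatable
signal treated as no amplification).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from wolcall.mlst import (
    LOCUS_NAMES,
    AlleleDatabase,
    MlstProfile,
    SequenceType,
    assign_group,
    profile_distance,
)

UNINFECTED = "uninfected"
SINGLE = "single"
DOUBLE = "double"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class MixtureProfile:
    """Per-locus allele sets observed in one specimen (1 or 2 alleles each).

    ``uncertain_loci`` flags loci where the double-peak pattern could not be
    read into a clean two-allele union (e.g. a chimeric component).
    """

    alleles_by_locus: Mapping[str, frozenset[str]]
    uncertain_loci: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = set(LOCUS_NAMES) - set(self.alleles_by_locus)
        if missing:
            raise ValueError(f"mixture missing loci: {sorted(missing)}")
        for locus, ids in self.alleles_by_locus.items():
            if locus in self.uncertain_loci:
                continue
            if not 1 <= len(ids) <= 2:
                raise ValueError(f"{locus}: mixture needs 1 or 2 alleles, got {sorted(ids)}")

    @property
    def is_true_mixture(self) -> bool:
        return bool(self.uncertain_loci) or any(
            len(ids) == 2 for ids in self.alleles_by_locus.values()
        )

    @classmethod
    def from_profiles(cls, p1: MlstProfile, p2: MlstProfile) -> "MixtureProfile":
        return cls(
            {
                locus: frozenset((p1[locus], p2[locus]))
                for locus in LOCUS_NAMES
            }
        )


@dataclass(frozen=True)
class InfectionState:
    """Resolved infection of one specimen.

    ``sts`` holds 0–2 ST ids; ``candidates`` lists alternative ST pairs when
    the resolution is ambiguous; ``notes`` carries diagnostics such as
    ``"weak-signal"`` or ``"gatB uncertain"``.
    """

    status: str
    sts: tuple[str, ...] = ()
    candidates: tuple[tuple[str, str], ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = {UNINFECTED: 0, SINGLE: 1, DOUBLE: 2}
        if self.status in expected and len(self.sts) != expected[self.status]:
            raise ValueError(f"{self.status} state with {len(self.sts)} STs")
        if self.status == DOUBLE and self.sts[0] == self.sts[1]:
            raise ValueError("double infection needs two distinct STs")


@dataclass
class SpecimenRecord:
    """One beetle: identity, mtDNA/nuclear markers and MLST observations."""

    specimen_id: str
    taxon: str
    region: str
    cox1_haplotype: str
    wg_genotype: str = ""
    observations: Mapping[str, str] = field(default_factory=dict)
    infection: InfectionState | None = None

    def __post_init__(self) -> None:
        if not self.cox1_haplotype:
            raise ValueError(f"{self.specimen_id}: empty cox1 haplotype")


class MalformedMixtureError(ValueError):
    """A mixture observation with an empty locus set."""


# --------------------------------------------------------------------------
# Observation parsing
# --------------------------------------------------------------------------

_FAINT = re.compile(r"^\?low$", re.IGNORECASE)


def parse_observations(
    observations: Mapping[str, str],
) -> tuple[str, MlstProfile | MixtureProfile | None, list[str]]:
    """Interpret raw per-locus tokens.

    Returns ``(kind, payload, notes)`` where kind is ``"none"`` (no usable
    amplification), ``"single"`` (a complete clean profile) or ``"mixture"``.
    Faint signals (``?low``) count as no amplification with a weak-signal
    note; a specimen amplifying only a subset of loci cleanly is likewise
    treated as lacking a confirmed infection.
    """
    notes: list[str] = []
    sets: dict[str, frozenset[str]] = {}
    uncertain: set[str] = set()
    n_faint = 0
    for locus in LOCUS_NAMES:
        token = (observations.get(locus) or "").strip()
        if not token:
            sets[locus] = frozenset()
        elif _FAINT.match(token):
            n_faint += 1
            sets[locus] = frozenset()
        elif token == "?":
            uncertain.add(locus)
            sets[locus] = frozenset()
        else:
            ids = frozenset(part.strip() for part in token.split("/"))
            if "" in ids:
                raise MalformedMixtureError(f"{locus}: malformed token {token!r}")
            sets[locus] = ids
    if n_faint:
        notes.append(f"weak-signal:{n_faint}")

    amplified = {l for l, s in sets.items() if s} | uncertain
    if not amplified:
        return "none", None, notes
    if len(amplified) < len(LOCUS_NAMES):
        notes.append(f"partial amplification ({len(amplified)}/5 loci); not typed")
        return "none", None, notes
    if not uncertain and all(len(s) == 1 for s in sets.values()):
        profile = MlstProfile(tuple(next(iter(sets[l])) for l in LOCUS_NAMES))
        return "single", profile, notes
    mixture = MixtureProfile(
        {l: sets[l] for l in LOCUS_NAMES}, uncertain_loci=frozenset(uncertain)
    )
    return "mixture", mixture, notes


# --------------------------------------------------------------------------
# ST table helpers
# --------------------------------------------------------------------------


class StTable:
    """Mutable collection of named STs with profile lookup and id minting."""

    def __init__(self, sts: Iterable[SequenceType] = ()) -> None:
        self._by_id: dict[str, SequenceType] = {}
        self._by_profile: dict[MlstProfile, SequenceType] = {}
        for st in sts:
            self.add(st)

    def add(self, st: SequenceType) -> None:
        if st.st_id in self._by_id:
            raise ValueError(f"duplicate ST id {st.st_id}")
        if st.profile in self._by_profile:
            raise ValueError(
                f"profile of {st.st_id} duplicates {self._by_profile[st.profile].st_id}"
            )
        self._by_id[st.st_id] = st
        self._by_profile[st.profile] = st

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, st_id: str) -> bool:
        return st_id in self._by_id

    def get(self, st_id: str) -> SequenceType:
        return self._by_id[st_id]

    def by_profile(self, profile: MlstProfile) -> SequenceType | None:
        return self._by_profile.get(profile)

    def nearest_distance(self, profile: MlstProfile) -> int:
        return min(profile_distance(profile, st.profile) for st in self)

    def mint_id(self, group: str) -> str:
        """Next free ``<group><n>`` id, n = smallest unused positive integer."""
        used = set()
        for st_id in self._by_id:
            m = re.fullmatch(re.escape(group) + r"(\d+)\w*", st_id)
            if m:
                used.add(int(m.group(1)))
        n = 1
        while n in used:
            n += 1
        return f"{group}{n}"


def _mint_sequence_type(
    profile: MlstProfile,
    table: StTable,
    provenance: str,
    extra_gatb_groups: Mapping[str, str] | None,
    db: AlleleDatabase | None,
) -> SequenceType:
    """Name a new profile: mosaic variants of a neighbour get its id + 'r'."""
    group = assign_group(profile, extra_gatb_groups)
    if db is not None:
        chimeric_loci = [
            locus
            for locus in LOCUS_NAMES
            if (locus, profile[locus]) in db
            and db.get(locus, profile[locus]).chimera_of is not None
        ]
        if chimeric_loci:
            for st in sorted(table, key=lambda s: s.st_id):
                if profile_distance(profile, st.profile) == 1 and all(
                    profile[l] == st.profile[l] for l in LOCUS_NAMES if l not in chimeric_loci
                ):
                    return SequenceType(st.st_id + "r", profile, group, "mosaic")
            return SequenceType(table.mint_id(group) + "r", profile, group, "mosaic")
    return SequenceType(table.mint_id(group), profile, group, provenance)


# --------------------------------------------------------------------------
# Resolution operations
# --------------------------------------------------------------------------


def resolve_single(
    profile: MlstProfile,
    st_table: StTable,
    extra_gatb_groups: Mapping[str, str] | None = None,
    db: AlleleDatabase | None = None,
) -> tuple[InfectionState, list[SequenceType]]:
    """Resolve a clean single-infection profile to an ST (minting if novel)."""
    st = st_table.by_profile(profile)
    if st is not None:
        return InfectionState(SINGLE, sts=(st.st_id,)), []
    minted = _mint_sequence_type(profile, st_table, "observed", extra_gatb_groups, db)
    st_table.add(minted)
    return (
        InfectionState(SINGLE, sts=(minted.st_id,), notes=("novel ST",)),
        [minted],
    )


@dataclass(frozen=True)
class _Candidate:
    """One consistent (anchor, partner) resolution of a mixture."""

    anchor: SequenceType
    partner_profile: MlstProfile
    partner: SequenceType | None  # None if the partner would be a new ST
    new_distance: int  # distance of a new partner to the nearest known ST; 0 if known

    @property
    def pair_key(self) -> frozenset[MlstProfile]:
        return frozenset((self.anchor.profile, self.partner_profile))


def _enumerate_candidates(
    mixture: MixtureProfile, st_table: StTable, max_new_dist: int
) -> list[_Candidate]:
    """All (anchor, partner) pairs whose locus-wise union equals the mixture.

    The anchor ranges over every ST already in the table (observed or
    previously deduced); given the anchor, the partner's profile is forced at
    every locus, so each anchor yields at most one candidate.  Loci flagged
    uncertain are excluded from the union constraint, and partners are then
    required to be known STs (no minting through an unread locus).
    """
    loci = [l for l in LOCUS_NAMES if l not in mixture.uncertain_loci]
    out: list[_Candidate] = []
    seen: set[frozenset[MlstProfile]] = set()
    for anchor in sorted(st_table, key=lambda s: s.st_id):
        partner_alleles: dict[str, set[str]] = {}
        ok = True
        for locus in loci:
            obs = mixture.alleles_by_locus[locus]
            a = anchor.profile[locus]
            if a not in obs:
                ok = False
                break
            rest = obs - {a}
            partner_alleles[locus] = set(rest) if rest else {a}
        if not ok:
            continue
        if mixture.uncertain_loci:
            # partner must be a known ST whose union with the anchor matches
            # the mixture at every readable locus
            for partner in sorted(st_table, key=lambda s: s.st_id):
                if partner.st_id == anchor.st_id:
                    continue
                if all(
                    frozenset((anchor.profile[l], partner.profile[l]))
                    == mixture.alleles_by_locus[l]
                    for l in loci
                ):
                    cand = _Candidate(anchor, partner.profile, partner, 0)
                    if cand.pair_key not in seen:
                        seen.add(cand.pair_key)
                        out.append(cand)
            continue
        partner_profile = MlstProfile(
            tuple(next(iter(partner_alleles[l])) for l in LOCUS_NAMES)
        )
        if partner_profile == anchor.profile:
            continue  # no second strain at any locus
        partner = st_table.by_profile(partner_profile)
        if partner is not None:
            cand = _Candidate(anchor, partner_profile, partner, 0)
        else:
            dist = st_table.nearest_distance(partner_profile)
            if dist > max_new_dist:
                continue
            cand = _Candidate(anchor, partner_profile, None, dist)
        if cand.pair_key not in seen:
            seen.add(cand.pair_key)
            out.append(cand)
    return out


def _ordered_pair(anchor_id: str, partner_id: str) -> tuple[str, str]:
    return tuple(sorted((anchor_id, partner_id)))  # type: ignore[return-value]


def deconvolve(
    mixture: MixtureProfile,
    st_table: StTable,
    max_new_dist: int = 1,
    single_freqs: Mapping[str, int] | None = None,
    extra_gatb_groups: Mapping[str, str] | None = None,
    db: AlleleDatabase | None = None,
    pick: str = "ranked",
) -> tuple[InfectionState, list[SequenceType]]:
    """Deconvolve a double-infection mixture into two sequence types.

    Candidates are all ST pairs whose locus-wise allele union reproduces the
    mixture, anchored on an ST already in the table; the partner may be known
    or a new profile within ``max_new_dist`` of a known ST.  A unique pair of
    two known STs resolves immediately.  Otherwise candidates needing one new
    ST are ranked by (distance of the new profile to the nearest known ST,
    descending single-infection frequency of the anchor, anchor id); with
    ``pick="ranked"`` the best candidate wins and the new ST is minted with
    provenance ``"deduced"``; with ``pick="unique"`` any multiplicity yields
    an ambiguous state listing all candidates.

    Mixtures with an uncertain (unreadable) locus are never resolved; they
    return an ambiguous state whose candidates are the known-ST pairs
    consistent with the readable loci.
    """
    if not mixture.is_true_mixture:
        raise MalformedMixtureError("not a mixture: no locus with two alleles")
    freqs = dict(single_freqs or {})
    cands = _enumerate_candidates(mixture, st_table, max_new_dist)

    if mixture.uncertain_loci:
        pairs = tuple(
            _ordered_pair(c.anchor.st_id, c.partner.st_id) for c in cands if c.partner
        )
        notes = tuple(f"{l} uncertain" for l in sorted(mixture.uncertain_loci))
        return InfectionState(AMBIGUOUS, candidates=pairs, notes=notes), []

    if not cands:
        return (
            InfectionState(AMBIGUOUS, notes=("no consistent ST pair",)),
            [],
        )

    known = [c for c in cands if c.partner is not None]
    if known:
        # rank all-known pairs by how strongly their members are attested as
        # single infections; a clear winner resolves, a dead tie is ambiguous
        def pair_freq(c: _Candidate) -> int:
            return freqs.get(c.anchor.st_id, 0) + freqs.get(c.partner.st_id, 0)

        known.sort(key=lambda c: (-pair_freq(c), c.anchor.st_id, c.partner.st_id))
        if len(known) == 1 or (
            pick == "ranked" and pair_freq(known[0]) > pair_freq(known[1])
        ):
            c = known[0]
            state = InfectionState(
                DOUBLE, sts=_ordered_pair(c.anchor.st_id, c.partner.st_id)
            )
            if len(known) > 1:
                state = replace(
                    state,
                    notes=("alternative pairs exist; resolved by single-infection frequency",),
                )
            return state, []
        pairs = tuple(_ordered_pair(c.anchor.st_id, c.partner.st_id) for c in known)
        return (
            InfectionState(AMBIGUOUS, candidates=pairs, notes=("multiple known pairs",)),
            [],
        )

    # every candidate needs one new ST
    if pick == "unique" and len(cands) > 1:
        pairs = tuple(_ordered_pair(c.anchor.st_id, f"<new:{c.partner_profile}>") for c in cands)
        return (
            InfectionState(AMBIGUOUS, candidates=pairs, notes=("multiple resolutions",)),
            [],
        )
    best = min(
        cands,
        key=lambda c: (c.new_distance, -freqs.get(c.anchor.st_id, 0), c.anchor.st_id),
    )
    minted = _mint_sequence_type(
        best.partner_profile, st_table, "deduced", extra_gatb_groups, db
    )
    st_table.add(minted)
    state = InfectionState(DOUBLE, sts=_ordered_pair(best.anchor.st_id, minted.st_id))
    return state, [minted]


def classify_cohort(
    records: Sequence[SpecimenRecord],
    st_table: StTable | Iterable[SequenceType],
    max_new_dist: int = 1,
    extra_gatb_groups: Mapping[str, str] | None = None,
    db: AlleleDatabase | None = None,
) -> tuple[list[SpecimenRecord], list[SequenceType]]:
    """Resolve every record of a cohort and return the carried-ST inventory.

    Single infections are resolved first (they establish the empirically
    observed STs and their frequencies); mixtures are then deconvolved to a
    fixpoint, preferring at every step the records that can be explained by
    STs already characterised:

    1. resolve every mixture whose unique consistent pair uses two known STs;
    2. else mint for the record with exactly one consistent candidate;
    3. else mint for the first record whose ranked best candidate is clear.

    Each minting can unlock step 1 for other records, so the passes repeat
    until nothing changes.  The returned inventory lists every ST carried by
    at least one specimen, observed before deduced before mosaic entries.
    The operation is idempotent: re-running on its own output is a no-op.
    """
    table = st_table if isinstance(st_table, StTable) else StTable(st_table)
    out = [replace(r) for r in records]

    parsed: dict[int, tuple[str, object, list[str]]] = {
        i: parse_observations(r.observations) for i, r in enumerate(out)
    }

    # pass 0: uninfected and clean singles
    single_freqs: dict[str, int] = {}
    for i, rec in enumerate(out):
        kind, payload, notes = parsed[i]
        if kind == "none":
            rec.infection = InfectionState(UNINFECTED, notes=tuple(notes))
        elif kind == "single":
            state, _ = resolve_single(payload, table, extra_gatb_groups, db)
            rec.infection = replace(state, notes=state.notes + tuple(notes))
            single_freqs[state.sts[0]] = single_freqs.get(state.sts[0], 0) + 1

    unresolved = [i for i, rec in enumerate(out) if rec.infection is None]
    # records with an unreadable locus are assessed last, once the ST table
    # has stabilised, so their candidate lists see every deduced ST
    uncertain = [i for i in unresolved if parsed[i][1].uncertain_loci]  # type: ignore[union-attr]
    pending = [i for i in unresolved if i not in uncertain]

    def attempt(i: int, pick: str) -> tuple[InfectionState, list[SequenceType]]:
        return deconvolve(
            parsed[i][1],  # type: ignore[arg-type]
            table,
            max_new_dist=max_new_dist,
            single_freqs=single_freqs,
            extra_gatb_groups=extra_gatb_groups,
            db=db,
            pick=pick,
        )

    while pending:
        # step 1: records resolvable (possibly by frequency ranking) without
        # minting any new ST
        progressed = False
        for i in list(pending):
            mixture = parsed[i][1]
            cands = _enumerate_candidates(mixture, table, max_new_dist)  # type: ignore[arg-type]
            if any(c.partner is not None for c in cands):
                state, _ = attempt(i, "ranked")
                out[i].infection = replace(state, notes=state.notes + tuple(parsed[i][2]))
                pending.remove(i)
                progressed = True
        if progressed:
            continue

        # step 2: mint for the first record (in input order) that has any
        # resolution; each minting can unlock step 1 for later records
        fell_back = False
        for i in list(pending):
            cands = _enumerate_candidates(parsed[i][1], table, max_new_dist)  # type: ignore[arg-type]
            if cands:
                state, _ = attempt(i, "ranked")
                out[i].infection = replace(state, notes=state.notes + tuple(parsed[i][2]))
                pending.remove(i)
                fell_back = True
                break
        if not fell_back:
            for i in list(pending):  # nothing explains these mixtures
                state, _ = attempt(i, "unique")
                out[i].infection = replace(state, notes=state.notes + tuple(parsed[i][2]))
                pending.remove(i)

    for i in uncertain:
        state, _ = attempt(i, "unique")
        out[i].infection = replace(state, notes=state.notes + tuple(parsed[i][2]))

    carried: set[str] = set()
    for rec in out:
        assert rec.infection is not None
        carried.update(rec.infection.sts)
    order = {"observed": 0, "deduced": 1, "mosaic": 2}
    inventory = sorted(
        (table.get(st_id) for st_id in carried),
        key=lambda st: (order.get(st.provenance, 3), st.st_id),
    )
    return out, inventory


def count_sequence_types(inventory: Iterable[SequenceType]) -> int:
    """Distinct STs in an inventory, not counting mosaic variants."""
    return sum(1 for st in inventory if st.provenance in ("observed", "deduced"))


# --------------------------------------------------------------------------
# Specimen table I/O
# --------------------------------------------------------------------------

SPECIMEN_COLUMNS = [
    "specimen_id", "taxon", "region", "cox1_haplotype", "wg_genotype", *LOCUS_NAMES,
]


def read_specimen_table(path: str) -> list[SpecimenRecord]:
    import csv

    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(SPECIMEN_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            records.append(
                SpecimenRecord(
                    specimen_id=row["specimen_id"],
                    taxon=row["taxon"],
                    region=row["region"],
                    cox1_haplotype=row["cox1_haplotype"],
                    wg_genotype=row["wg_genotype"],
                    observations={l: row[l] for l in LOCUS_NAMES},
                )
            )
    return records


def write_specimen_table(records: Sequence[SpecimenRecord], path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SPECIMEN_COLUMNS)
        for r in records:
            writer.writerow(
                [r.specimen_id, r.taxon, r.region, r.cox1_haplotype, r.wg_genotype]
                + [r.observations.get(l, "") for l in LOCUS_NAMES]
            )


def write_infection_table(records: Sequence[SpecimenRecord], path: str) -> None:
    """Resolved-infection CSV: identity columns plus status, STs and notes."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["specimen_id", "taxon", "region", "cox1_haplotype", "wg_genotype",
             "status", "sts", "candidates", "notes"]
        )
        for r in records:
            inf = r.infection
            writer.writerow(
                [r.specimen_id, r.taxon, r.region, r.cox1_haplotype, r.wg_genotype,
                 inf.status if inf else "",
                 "+".join(inf.sts) if inf else "",
                 ";".join("+".join(p) for p in inf.candidates) if inf else "",
                 ";".join(inf.notes) if inf else ""]
            )
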