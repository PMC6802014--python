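"""Wolbachia MLST typing: allele databases, allele calling, ST profiles.

The five-locus MLST scheme of Baldo et al. characterises a *Wolbachia* strain
by the allele identities at *gatB*, *coxA*, *hcpA*, *ftsZ* and *fbpA*; a
unique five-allele combination is a sequence type (ST).  This module provides

- the locus panel with the canonical fragment sizes,
- an allele database keyed by (locus, allele id) with per-locus FASTA I/O,
- trimming of raw Sanger reads to the MLST fragment window,
- allele calling from clean fragments, including two-allele mixtures read
  from IUPAC double-peak codes,
- ST profile containers, Hamming-type inter-profile distance, group
  assignment by the *gatB* allele, and single-breakpoint chimera detection.

Coordinates are 0-based half-open; sequences are stored on the forward strand
of the MLST reference orientation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class MlstLocus(NamedTuple):
    """One locus of the MLST panel with its canonical fragment size (bp)."""

    name: str
    fragment_length: int


#: The five-locus Wolbachia MLST panel with canonical fragment sizes.
LOCI: tuple[MlstLocus, ...] = (
    MlstLocus("gatB", 369),
    MlstLocus("coxA", 402),
    MlstLocus("hcpA", 444),
    MlstLocus("ftsZ", 435),
    MlstLocus("fbpA", 429),
)

LOCUS_NAMES: tuple[str, ...] = tuple(l.name for l in LOCI)
LOCUS_BY_NAME: dict[str, MlstLocus] = {l.name: l for l in LOCI}

#: IUPAC nucleotide codes -> base sets (unambiguous bases map to themselves).
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}


class UntypeableSequenceError(ValueError):
    """Raised when a raw read cannot be aligned to any allele of the locus."""


class UnmappedGatbAlleleError(KeyError):
    """Raised when a profile's gatB allele has no group assignment."""


@dataclass(frozen=True)
class Allele:
    """One allele: a locus, an identifier and its fragment-length sequence.

    Identifiers are either established numeric ids from the curated MLST
    database (e.g. ``"33"``) or provisional lower-case letters for alleles
    first seen in this host system (e.g. ``"a"``).
    """

    locus: str
    allele_id: str
    sequence: str
    chimera_of: tuple[str, str] | None = None  # parents, for mosaic alleles

    def __post_init__(self) -> None:
        expected = LOCUS_BY_NAME[self.locus].fragment_length
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.locus} allele {self.allele_id!r}: sequence length "
                f"{len(self.sequence)} != fragment length {expected}"
            )


class AlleleDatabase:
    """Alleles grouped by locus, with total lookup on stored entries.

    A local stand-in for the curated PubMLST *Wolbachia* database: alleles are
    registered per locus, sequences within a locus must be pairwise distinct,
    and (locus, allele id) pairs are unique.
    """

    def __init__(self, alleles: Iterable[Allele] = (), provenance: str = "") -> None:
        self.provenance = provenance
        self._by_key: dict[tuple[str, str], Allele] = {}
        self._by_locus: dict[str, list[Allele]] = {name: [] for name in LOCUS_NAMES}
        for allele in alleles:
            self.add(allele)

    def add(self, allele: Allele) -> None:
        key = (allele.locus, allele.allele_id)
        if key in self._by_key:
            raise ValueError(f"duplicate allele {key}")
        for other in self._by_locus[allele.locus]:
            if other.sequence == allele.sequence:
                raise ValueError(
                    f"{allele.locus} allele {allele.allele_id!r} duplicates the "
                    f"sequence of allele {other.allele_id!r}"
                )
        self._by_key[key] = allele
        self._by_locus[allele.locus].append(allele)

    def get(self, locus: str, allele_id: str) -> Allele:
        return self._by_key[(locus, allele_id)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._by_key

    def alleles_for(self, locus: str) -> list[Allele]:
        return list(self._by_locus[locus])

    def allele_ids(self, locus: str) -> list[str]:
        return [a.allele_id for a in self._by_locus[locus]]

    def mint_provisional_id(self, locus: str) -> str:
        """Next free single-letter provisional id (a, b, c, ...) for a locus."""
        used = set(self.allele_ids(locus))
        for letter in "abcdefghijklmnopqrstuvwxyz":
            if letter not in used:
                return letter
        raise RuntimeError(f"provisional id space exhausted for {locus}")

    # ---- FASTA I/O: one file per locus, headers "<locus>_<allele_id>" ----

    @classmethod
    def from_fasta(cls, paths: Mapping[str, str], provenance: str = "") -> "AlleleDatabase":
        """Load a database from one FASTA file per locus.

        ``paths`` maps locus name to file path. Record ids must follow the
        ``locus_alleleid`` convention, e.g. ``gatB_33``.
        """
        db = cls(provenance=provenance)
        for locus, path in paths.items():
            for rec in SeqIO.parse(path, "fasta"):
                prefix = f"{locus}_"
                if not rec.id.startswith(prefix):
                    raise ValueError(f"{path}: header {rec.id!r} does not start with {prefix!r}")
                db.add(Allele(locus, rec.id[len(prefix):], str(rec.seq).upper()))
        return db

    def to_fasta(self, directory: str) -> dict[str, str]:
        """Write one FASTA per locus into ``directory``; returns the path map."""
        import os

        paths = {}
        os.makedirs(directory, exist_ok=True)
        for locus in LOCUS_NAMES:
            path = os.path.join(directory, f"{locus}.fasta")
            records = [
                SeqRecord(Seq(a.sequence), id=f"{locus}_{a.allele_id}", description="")
                for a in self._by_locus[locus]
            ]
            SeqIO.write(records, path, "fasta")
            paths[locus] = path
        return paths


@dataclass(frozen=True, order=True)
class MlstProfile:
    """A complete five-locus allele profile, hashable and comparable by value.

    ``alleles`` holds the allele ids in canonical locus order
    (gatB, coxA, hcpA, ftsZ, fbpA).
    """

    alleles: tuple[str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(LOCI):
            raise ValueError("profile must cover all five loci")

    @classmethod
    def from_mapping(cls, alleles_by_locus: Mapping[str, str]) -> "MlstProfile":
        missing = set(LOCUS_NAMES) - set(alleles_by_locus)
        if missing:
            raise ValueError(f"profile missing loci: {sorted(missing)}")
        return cls(tuple(alleles_by_locus[name] for name in LOCUS_NAMES))

    def __getitem__(self, locus: str) -> str:
        return self.alleles[LOCUS_NAMES.index(locus)]

    @property
    def alleles_by_locus(self) -> dict[str, str]:
        return dict(zip(LOCUS_NAMES, self.alleles))

    def __str__(self) -> str:
        return ",".join(self.alleles)


@dataclass(frozen=True)
class SequenceType:
    """A named ST: an MLST profile plus its group and provenance.

    ``provenance`` is ``"observed"`` for STs recognised directly from single
    infections, ``"deduced"`` for profiles implied by double-infection
    subtraction, and ``"mosaic"`` for variants carrying a chimeric allele.
    """

    st_id: str
    profile: MlstProfile
    group: str
    provenance: str = "observed"


@dataclass(frozen=True)
class ChimeraReport:
    """Outcome of single-breakpoint chimera detection for one fragment."""

    locus: str
    is_chimeric: bool
    parent_ids: tuple[str, str] | None = None
    breakpoint_window: tuple[int, int] | None = None  # 0-based half-open


@dataclass(frozen=True)
class AlleleCall:
    """Result of calling one fragment: known / novel / mixture / unresolved."""

    locus: str
    kind: str  # "known" | "novel" | "mixture" | "unresolved"
    allele_id: str | None = None
    mixture: tuple[str, str] | None = None
    diagnostics: str = ""


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def trim_to_fragment(
    raw_sequence: str,
    locus: MlstLocus | str,
    db: AlleleDatabase,
    min_identity: float = 0.80,
) -> str:
    """Trim a raw read to the canonical MLST fragment window.

    Scans every window of ``fragment_length`` over the raw sequence and keeps
    the one with the highest identity to its best-matching database allele;
    ties resolve to the leftmost window.  Raises
    :class:`UntypeableSequenceError` if no window reaches ``min_identity`` —
    a read that far from every known allele is an off-target amplicon rather
    than a divergent Wolbachia allele.
    """
    if isinstance(locus, str):
        locus = LOCUS_BY_NAME[locus]
    raw = raw_sequence.upper()
    flen = locus.fragment_length
    if len(raw) < flen:
        raise ValueError(
            f"raw sequence ({len(raw)} bp) shorter than {locus.name} fragment ({flen} bp)"
        )
    alleles = db.alleles_for(locus.name)
    if not alleles:
        raise ValueError(f"database has no alleles for {locus.name}")

    best_score, best_start = -1, 0
    for start in range(len(raw) - flen + 1):
        window = raw[start : start + flen]
        score = max(
            sum(a == b for a, b in zip(window, allele.sequence)) for allele in alleles
        )
        if score > best_score:  # strict > keeps the leftmost best window
            best_score, best_start = score, start
    if best_score / flen < min_identity:
        raise UntypeableSequenceError(
            f"no {flen} bp window of the read reaches {min_identity:.0%} identity "
            f"to any {locus.name} allele (best {best_score / flen:.1%})"
        )
    return raw[best_start : best_start + flen]


def call_allele(locus: str, fragment: str, db: AlleleDatabase) -> AlleleCall:
    """Call one fragment as a known allele, a novel allele, or a two-allele mixture.

    A fragment without ambiguity codes either matches a stored allele exactly
    (``known``) or is a ``novel`` allele.  A fragment with IUPAC ambiguity
    codes is a ``mixture`` of alleles (a1, a2) iff at *every* position the
    observed code equals exactly the union of the two alleles' bases — the
    double-peak logic of superimposed Sanger traces.  Anything else (e.g. a
    code whose bases no allele pair explains) is ``unresolved``.
    """
    frag = fragment.upper()
    flen = LOCUS_BY_NAME[locus].fragment_length
    if len(frag) != flen:
        raise ValueError(f"{locus} fragment length {len(frag)} != {flen}")

    has_ambiguity = any(c not in "ACGT" for c in frag)
    if not has_ambiguity:
        for allele in db.alleles_for(locus):
            if allele.sequence == frag:
                return AlleleCall(locus, "known", allele_id=allele.allele_id)
        return AlleleCall(locus, "novel", diagnostics="no exact match in database")

    try:
        observed = [IUPAC_TO_BASES[c] for c in frag]
    except KeyError as exc:
        return AlleleCall(locus, "unresolved", diagnostics=f"invalid symbol {exc}")

    matches = []
    for a1, a2 in itertools.combinations(db.alleles_for(locus), 2):
        if all(
            obs == frozenset((b1, b2))
            for obs, b1, b2 in zip(observed, a1.sequence, a2.sequence)
        ):
            matches.append(tuple(sorted((a1.allele_id, a2.allele_id))))
    if len(matches) == 1:
        return AlleleCall(locus, "mixture", mixture=matches[0])
    if not matches:
        return AlleleCall(
            locus, "unresolved",
            diagnostics="ambiguity codes not explained by any allele pair "
            "(possible >2-way mixture or chimeric component)",
        )
    return AlleleCall(
        locus, "unresolved",
        diagnostics=f"ambiguity pattern consistent with several pairs: {matches}",
    )


#: Group assignment by gatB allele: a/b -> wCallA, c -> wCallB, d -> wCallC.
DEFAULT_GATB_GROUPS: dict[str, str] = {
    "a": "wCallA",
    "b": "wCallA",
    "c": "wCallB",
    "d": "wCallC",
}


def assign_group(
    profile: MlstProfile, extra_gatb_groups: Mapping[str, str] | None = None
) -> str:
    """Assign a profile to one of the main strain groups by its gatB allele.

    The three groups (wCallA–wCallC) are mostly defined by the gatB allele;
    ``extra_gatb_groups`` lets callers extend the mapping, e.g. for a chimeric
    gatB variant that still belongs with one group.
    """
    mapping = dict(DEFAULT_GATB_GROUPS)
    if extra_gatb_groups:
        mapping.update(extra_gatb_groups)
    gatb = profile["gatB"]
    try:
        return mapping[gatb]
    except KeyError:
        raise UnmappedGatbAlleleError(
            f"gatB allele {gatb!r} has no group assignment; extend the mapping"
        ) from None


def profile_distance(p1: MlstProfile, p2: MlstProfile) -> int:
    """Number of loci (0–5) at which two profiles carry different alleles."""
    return sum(a != b for a, b in zip(p1.alleles, p2.alleles))


def detect_chimera(fragment: str, locus: str, db: AlleleDatabase) -> ChimeraReport:
    """Test whether a fragment is a single-breakpoint mosaic of two alleles.

    The fragment is chimeric iff some ordered allele pair (x, y) and
    breakpoint b reproduce it exactly as ``x[:b] + y[b:]`` with zero
    mismatches, with neither parent matching the whole fragment alone.  The
    reported ``breakpoint_window`` is the maximal half-open interval of
    equally valid breakpoints for the winning pair; among pairs, the one with
    the smallest window start wins, then lexicographic allele ids.
    """
    frag = fragment.upper()
    flen = LOCUS_BY_NAME[locus].fragment_length
    if len(frag) != flen:
        raise ValueError(f"{locus} fragment length {len(frag)} != {flen}")

    best: tuple[int, str, str, tuple[int, int]] | None = None
    for x, y in itertools.permutations(db.alleles_for(locus), 2):
        # prefix match length from x, suffix match length from y
        prefix = 0
        while prefix < flen and frag[prefix] == x.sequence[prefix]:
            prefix += 1
        suffix_start = flen
        while suffix_start > 0 and frag[suffix_start - 1] == y.sequence[suffix_start - 1]:
            suffix_start -= 1
        # valid breakpoints b satisfy b <= prefix and b >= suffix_start
        if suffix_start > prefix:
            continue  # no zero-mismatch single breakpoint for this pair
        lo, hi = suffix_start, prefix + 1
        # reject degenerate "chimeras" identical to a single parent
        if frag in (x.sequence, y.sequence):
            continue
        # breakpoints at the extreme ends mean the fragment equals one parent
        window = (max(lo, 1), min(hi, flen))
        if window[0] >= window[1]:
            continue
        key = (window[0], x.allele_id, y.allele_id)
        if best is None or key < (best[0], best[1], best[2]):
            best = (window[0], x.allele_id, y.allele_id, window)
    if best is None:
        return ChimeraReport(locus, is_chimeric=False)
    _, xid, yid, window = best
    return ChimeraReport(locus, True, parent_ids=(xid, yid), breakpoint_window=window)


# --------------------------------------------------------------------------
# ST profile table I/O (PubMLST-style TSV)
# --------------------------------------------------------------------------

ST_TABLE_COLUMNS = ["ST", *LOCUS_NAMES, "group", "provenance"]


def read_st_table(path: str) -> list[SequenceType]:
    """Read an ST profile table (TSV: ST, gatB..fbpA, group, provenance)."""
    import csv

    sts = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ST_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            profile = MlstProfile.from_mapping({n: row[n] for n in LOCUS_NAMES})
            sts.append(SequenceType(row["ST"], profile, row["group"], row["provenance"]))
    return sts


def write_st_table(sts: Sequence[SequenceType], path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ST_TABLE_COLUMNS)
        for st in sts:
            writer.writerow([st.st_id, *st.profile.alleles, st.group, st.provenance])
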